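"""Regularized linear logistic-regression decoding of single-trial ERPs.

The decoder is a linear model on vectorized epochs: the decision value is

    f(x) = wᵀx + b

whose sign predicts the trial class (deviant ``+`` vs standard ``−``) and
whose logistic transform ``p(+|x) = 1 / (1 + e^(−f))`` is the posterior
probability that a deviant was observed.  Training minimizes the mean
logistic loss plus a ridge penalty ``λ‖w‖²`` with ``λ = c · v̄`` where
``v̄`` is the mean per-feature variance of the training data — making the
regularization weight ``c`` unitless with respect to the μV scale of the
features.  The bias is unpenalized.

The public surface follows the Model/Results convention:
:class:`MismatchDecoder` is built from data, ``fit`` / ``fit_grid`` return
a :class:`DecoderResults` carrying estimates, diagnostics and a
``summary()`` table, and cross-validation / grid-search hang off the
model object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold

from .containers import EpochSet, FeatureMatrix, vectorize

__all__ = [
    "TrainConfig",
    "TrialDecision",
    "MismatchDecoder",
    "DecoderResults",
    "CrossValidationResult",
    "train",
    "cross_validate",
    "grid_search_c",
]

#: The default regularization grid.  The value 0 denotes an
#: unregularized fit (λ = 0).
DEFAULT_C_GRID = (0.001, 0.01, 0.1, 0, 1, 10, 1000)


@dataclass(frozen=True)
class TrainConfig:
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    folds: int = 10
    seed: int = 0
    tol: float = 1e-5
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if len(self.c_grid) == 0:
            raise ValueError("c_grid must be non-empty")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class TrialDecision:
    """One trial's decision value, predicted class, and posterior."""

    f: float
    predicted: str  # "+" or "-"
    posterior: float  # p(+|x)


class ConvergenceError(RuntimeError):
    pass


def _as_xy(features, labels=None) -> tuple[np.ndarray, np.ndarray, dict | None]:
    if isinstance(features, EpochSet):
        features = vectorize(features)
    if isinstance(features, FeatureMatrix):
        X = features.X
        y = features.y if labels is None else np.asarray(labels)
        fp = features.fingerprint
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            raise ValueError("labels required for a bare feature array")
        y = np.asarray(labels)
        fp = None
    y = np.where(np.asarray(y) > 0, 1, -1)
    return X, y, fp


def _logistic_objective(params, X, y, lam):
    w, b = params[:-1], params[-1]
    f = X @ w + b
    z = y * f
    loss = np.mean(np.logaddexp(0.0, -z)) + lam * (w @ w)
    # d/dz log(1+e^(-z)) = -sigmoid(-z)
    s = _sigmoid(-z)
    coef = -(y * s) / len(y)
    grad_w = X.T @ coef + 2.0 * lam * w
    grad_b = coef.sum()
    return loss, np.concatenate([grad_w, [grad_b]])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class MismatchDecoder:
    """Binary deviant-vs-standard decoder on vectorized epoch features.

    Parameters
    ----------
    features : EpochSet, FeatureMatrix or ndarray (epochs × features)
        Training data in μV.
    labels : array-like, optional
        Class labels in {−1, +1} (+1 = deviant).  Taken from the
        container when omitted.
    """

    def __init__(self, features, labels=None):
        X, y, fingerprint = _as_xy(features, labels)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present for training")
        self.X = X
        self.y = y
        self.fingerprint = fingerprint
        self.feature_variance = float(X.var(axis=0).mean())

    @classmethod
    def from_epochs(cls, epochs: EpochSet) -> "MismatchDecoder":
        return cls(vectorize(epochs))

    # -- fitting ----------------------------------------------------------

    def fit(self, c: float = 1.0, tol: float = 1e-5,
            max_iter: int = 2000, **meta) -> "DecoderResults":
        """Fit at a fixed regularization weight ``c``.

        ``λ = c × mean per-feature variance``; ``c = 0`` is an
        unregularized fit.
        """
        lam = c * self.feature_variance
        x0 = np.zeros(self.X.shape[1] + 1)
        res = minimize(
            _logistic_objective, x0, args=(self.X, self.y, lam),
            jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
        )
        grad_norm = float(np.max(np.abs(res.jac)))
        if grad_norm > 100 * tol and not res.success:
            raise ConvergenceError(
                f"optimizer stopped after {res.nit} iterations with "
                f"gradient norm {grad_norm:.3g} (tol {tol:g})"
            )
        w, b = res.x[:-1], float(res.x[-1])
        return DecoderResults(
            w=w, b=b, c=float(c), lam=float(lam),
            fingerprint=self.fingerprint,
            feature_variance=self.feature_variance,
            n_obs=len(self.y), n_iter=int(res.nit),
            grad_norm=grad_norm, meta=dict(meta),
        )

    def fit_grid(self, cfg: TrainConfig | None = None) -> "DecoderResults":
        """Grid-search ``c`` by cross-validation, then fit on all data."""
        cfg = cfg or TrainConfig()
        best_c, rates = grid_search_c(self.X, self.y, cfg)
        results = self.fit(best_c, tol=cfg.tol, max_iter=cfg.max_iter)
        results.meta["grid_rates"] = rates
        results.meta["cv_rate"] = rates[best_c]
        return results

    # -- evaluation -------------------------------------------------------

    def cross_validate(self, cfg: TrainConfig | None = None,
                       c: float = 1.0) -> "CrossValidationResult":
        cfg = cfg or TrainConfig()
        return cross_validate(self.X, self.y, cfg, c=c)


@dataclass
class DecoderResults:
    """Fitted decoder: weights, bias, regularization and diagnostics."""

    w: np.ndarray
    b: float
    c: float
    lam: float
    fingerprint: dict | None
    feature_variance: float
    n_obs: int
    n_iter: int
    grad_norm: float
    meta: dict = field(default_factory=dict)

    # -- prediction -------------------------------------------------------

    def decision_value(self, x) -> float | np.ndarray:
        """f(x) = wᵀx + b for one feature vector or a matrix of rows."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            if x.shape[0] != self.w.shape[0]:
                raise ValueError(
                    f"feature vector length {x.shape[0]} does not match "
                    f"model ({self.w.shape[0]})"
                )
            return float(x @ self.w + self.b)
        # Row-wise reduction, identical to the streaming path, so online
        # tracking reproduces batch decision values bit-exactly.
        return np.fromiter(
            (float(row @ self.w + self.b) for row in np.ascontiguousarray(x)),
            dtype=float, count=len(x),
        )

    def posterior(self, x) -> float | np.ndarray:
        """p(+|x) = 1 / (1 + e^(−f(x)))."""
        f = self.decision_value(x)
        p = _sigmoid(np.asarray(f, dtype=float))
        return float(p) if np.isscalar(f) else p

    def predict(self, x) -> str | np.ndarray:
        """Class prediction by the sign of f; ties (f = 0) predict ``−``."""
        f = self.decision_value(x)
        if np.isscalar(f):
            return "+" if f > 0 else "-"
        return np.where(np.asarray(f) > 0, "+", "-")

    def decide(self, x) -> TrialDecision:
        f = float(self.decision_value(x))
        return TrialDecision(f=f, predicted="+" if f > 0 else "-",
                             posterior=float(_sigmoid(np.array(f))))

    def accuracy(self, features, labels=None) -> float:
        X, y, _ = _as_xy(features, labels)
        f = self.decision_value(X)
        pred = np.where(f > 0, 1, -1)
        return float(np.mean(pred == y))

    def weight_map(self) -> np.ndarray:
        """Weights reshaped to (channels, samples) when a layout is known."""
        if not self.fingerprint:
            raise ValueError("no feature layout fingerprint available")
        return self.w.reshape(self.fingerprint["m"], self.fingerprint["n"])

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Mismatch decoder (regularized linear logistic regression)",
            "=" * 58,
            f"{'observations':<28}{self.n_obs}",
            f"{'features':<28}{len(self.w)}",
            f"{'regularization c':<28}{self.c:g}",
            f"{'penalty lambda':<28}{self.lam:.6g}",
            f"{'mean feature variance':<28}{self.feature_variance:.6g}",
            f"{'bias b':<28}{self.b:.6g}",
            f"{'|w|':<28}{np.linalg.norm(self.w):.6g}",
            f"{'optimizer iterations':<28}{self.n_iter}",
            f"{'final gradient norm':<28}{self.grad_norm:.3g}",
        ]
        if "cv_rate" in self.meta:
            lines.append(f"{'cross-validation rate':<28}{self.meta['cv_rate']:.4f}")
        if "grid_rates" in self.meta:
            lines.append("grid search (c : CV rate):")
            for c, r in self.meta["grid_rates"].items():
                lines.append(f"    {c:<10g}{r:.4f}")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "w": self.w.tolist(), "b": self.b, "c": self.c, "lam": self.lam,
            "fingerprint": self.fingerprint,
            "feature_variance": self.feature_variance,
            "n_obs": self.n_obs, "n_iter": self.n_iter,
            "grad_norm": self.grad_norm, "meta": self.meta,
        })

    @classmethod
    def from_json(cls, text: str) -> "DecoderResults":
        d = json.loads(text)
        d["w"] = np.asarray(d["w"], dtype=float)
        return cls(**d)

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path: str) -> "DecoderResults":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class CrossValidationResult:
    mean_rate: float
    fold_rates: np.ndarray
    decisions: np.ndarray  # out-of-fold decision values, input order
    fold_of: np.ndarray  # fold index per observation
    c: float


def train(features, labels=None, c: float = 1.0,
          cfg: TrainConfig | None = None) -> DecoderResults:
    """Functional form of :meth:`MismatchDecoder.fit`."""
    cfg = cfg or TrainConfig()
    return MismatchDecoder(features, labels).fit(
        c, tol=cfg.tol, max_iter=cfg.max_iter
    )


def cross_validate(features, labels=None, cfg: TrainConfig | None = None,
                   c: float = 1.0) -> CrossValidationResult:
    """Stratified, seeded k-fold cross-validation.

    Every observation is tested exactly once; the reported rate is the
    arithmetic mean of the fold rates, and the out-of-fold decision
    values are retained for downstream sorting and multi-trial fusion.
    """
    cfg = cfg or TrainConfig()
    X, y, _ = _as_xy(features, labels)
    counts = np.bincount((y > 0).astype(int))
    if counts.min() < cfg.folds:
        raise ValueError(
            f"smallest class has {counts.min()} examples; cannot stratify "
            f"into {cfg.folds} folds"
        )
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True,
                          random_state=cfg.seed)
    fold_rates = []
    decisions = np.empty(len(y))
    fold_of = np.empty(len(y), dtype=int)
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = MismatchDecoder(X[tr], y[tr]).fit(
            c, tol=cfg.tol, max_iter=cfg.max_iter
        )
        f = model.decision_value(X[te])
        pred = np.where(f > 0, 1, -1)
        fold_rates.append(float(np.mean(pred == y[te])))
        decisions[te] = f
        fold_of[te] = fold
    return CrossValidationResult(
        mean_rate=float(np.mean(fold_rates)),
        fold_rates=np.asarray(fold_rates),
        decisions=decisions, fold_of=fold_of, c=c,
    )


def grid_search_c(features, labels=None, cfg: TrainConfig | None = None
                  ) -> tuple[float, dict[float, float]]:
    """Full cross-validation per grid value; ties break toward larger c."""
    cfg = cfg or TrainConfig()
    X, y, _ = _as_xy(features, labels)
    rates: dict[float, float] = {}
    for c in cfg.c_grid:
        rates[c] = cross_validate(X, y, cfg, c=c).mean_rate
    best_rate = max(rates.values())
    best_c = max(c for c, r in rates.items() if r >= best_rate - 1e-12)
    return float(best_c), rates
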