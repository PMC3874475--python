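"""Statistics and feature-evaluation tools for the decoding framework.

Covers: binomial confidence intervals around chance level, label-permutation
tests, per-feature AUC maps with |AUC − 0.5| masking, spatial/temporal
searchlights with incremental ranked inclusion, ERP-component time-window
restriction, multi-trial decision fusion, generalization harnesses and
learning curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .containers import EpochSet, vectorize
from .decode import (CrossValidationResult, MismatchDecoder, TrainConfig,
                     TrialDecision, _sigmoid, cross_validate)

__all__ = [
    "binomial_ci",
    "permutation_test",
    "PermutationResult",
    "AucMap",
    "auc_map",
    "auc_mask",
    "SearchlightResult",
    "searchlight",
    "incremental_selection",
    "restrict_window",
    "combine_trials",
    "multi_trial_accuracy",
    "generalization_eval",
    "learning_curve",
]


# --------------------------------------------------------------------------
# Chance-level statistics
# --------------------------------------------------------------------------

def binomial_ci(k: int, alpha: float = 0.05, p: float = 0.5,
                method: str = "wald") -> float:
    """Half-width of the binomial confidence interval around ``p``.

    ``wald`` is the normal-approximation interval
    ``z_{1−α/2} · sqrt(p(1−p)/k)`` (±3.1% at k=1000); ``wilson`` is the
    score interval, which better matches small-k behaviour (±9.6% at
    k=100).  Returned as a proportion.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    z = norm.ppf(1 - alpha / 2.0)
    if method == "wald":
        return float(z * np.sqrt(p * (1 - p) / k))
    if method == "wilson":
        denom = 1 + z**2 / k
        half = z * np.sqrt(p * (1 - p) / k + z**2 / (4 * k**2))
        return float(half / denom)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    p_value: float  # count / n_perm, exactly as defined (no +1 smoothing)
    count: int
    n_perm: int

    @property
    def formatted_p(self) -> str:
        if self.count == 0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.p_value:g}"


def permutation_test(features, labels, eval_fn, n_perm: int = 10000,
                     seed: int = 0) -> PermutationResult:
    """Label-shuffling null distribution for a performance statistic.

    ``p = #(permuted score ≥ observed) / n_perm``; a zero count is
    reported as ``< 1/n_perm`` via :attr:`PermutationResult.formatted_p`.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = float(eval_fn(features, labels))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if float(eval_fn(features, perm)) >= observed:
            count += 1
    return PermutationResult(observed=observed, p_value=count / n_perm,
                             count=count, n_perm=n_perm)


# --------------------------------------------------------------------------
# AUC maps and masking
# --------------------------------------------------------------------------

@dataclass
class AucMap:
    """Per-(channel, time) discriminability of deviant vs standard trials."""

    auc: np.ndarray  # (m, n) in [0, 1]
    channel_labels: tuple[str, ...]
    times: np.ndarray

    @property
    def mask_values(self) -> np.ndarray:
        """|AUC − 0.5|: distance from the no-discrimination line."""
        return np.abs(self.auc - 0.5)


def auc_map(epochs: EpochSet) -> AucMap:
    """Rank-based (Mann-Whitney) AUC per spatio-temporal feature.

    Deviant trials are the positive class; ties are handled by midranks,
    so the result equals exhaustive pair counting exactly.
    """
    fm = vectorize(epochs)
    pos = fm.y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes required for an AUC map")
    ranks = rankdata(fm.X, axis=0)
    r_pos = ranks[pos].sum(axis=0)
    auc = (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return AucMap(
        auc=auc.reshape(fm.m, fm.n),
        channel_labels=fm.channel_labels,
        times=fm.times.copy(),
    )


def auc_mask(amap: AucMap, mask_value: float) -> np.ndarray:
    """Feature columns (channel-major) with |AUC − 0.5| ≥ the mask value."""
    return np.flatnonzero(amap.mask_values.ravel() >= mask_value)


# --------------------------------------------------------------------------
# Searchlights
# --------------------------------------------------------------------------

@dataclass
class SearchlightResult:
    axis: str  # "spatial" | "temporal"
    units: list  # channel labels or time points (ms)
    rates: np.ndarray  # CV rate per unit
    ranking: np.ndarray  # unit indices, best first (ties by unit index)


def _unit_feature_sets(epochs: EpochSet, axis: str):
    if axis == "spatial":
        idx = epochs.montage.eeg_indices
        units = [epochs.montage.labels[i] for i in idx]
        blocks = [epochs.data[:, i, :] for i in idx]
    elif axis == "temporal":
        units = [float(t) for t in epochs.times]
        blocks = [epochs.data[:, :, j] for j in range(epochs.n)]
    else:
        raise ValueError("axis must be 'spatial' or 'temporal'")
    return units, blocks


def searchlight(epochs: EpochSet, axis: str,
                cv_cfg: TrainConfig | None = None,
                c: float = 1.0) -> SearchlightResult:
    """Cross-validated decoding restricted to one channel or one time point.

    Spatial: one analysis per EEG channel using all time points.
    Temporal: one analysis per time point using all EEG channels.
    """
    cv_cfg = cv_cfg or TrainConfig()
    units, blocks = _unit_feature_sets(epochs, axis)
    y = epochs.y
    rates = np.array([
        cross_validate(block.reshape(len(y), -1), y, cv_cfg, c=c).mean_rate
        for block in blocks
    ])
    # Best first; ties broken by unit index (stable sort on negated rates).
    ranking = np.argsort(-rates, kind="stable")
    return SearchlightResult(axis=axis, units=units, rates=rates,
                             ranking=ranking)


def incremental_selection(result: SearchlightResult, epochs: EpochSet,
                          cv_cfg: TrainConfig | None = None,
                          c: float = 1.0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """CV rate using the top-1, top-2, … ranked units.

    Returns ``(curve, best_subset)`` where ``curve[k-1]`` is the rate with
    the k best units and ``best_subset`` is the unit-index set at the
    argmax (first maximum for ties).
    """
    cv_cfg = cv_cfg or TrainConfig()
    _, blocks = _unit_feature_sets(epochs, result.axis)
    y = epochs.y
    curve = np.empty(len(result.ranking))
    for j in range(1, len(result.ranking) + 1):
        chosen = result.ranking[:j]
        X = np.concatenate(
            [blocks[i].reshape(len(y), -1) for i in chosen], axis=1
        )
        curve[j - 1] = cross_validate(X, y, cv_cfg, c=c).mean_rate
    best = int(np.argmax(curve)) + 1
    return curve, result.ranking[:best]


def restrict_window(epochs: EpochSet, window_ms: tuple[float, float]
                    ) -> EpochSet:
    """Keep samples whose time lies in [start, end] (inclusive on the grid)."""
    start, end = window_ms
    mask = (epochs.times >= start - 1e-9) & (epochs.times <= end + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    from dataclasses import replace
    return replace(
        epochs, data=epochs.data[:, :, mask], times=epochs.times[mask]
    )


# --------------------------------------------------------------------------
# Multi-trial fusion
# --------------------------------------------------------------------------

def combine_trials(decisions) -> TrialDecision:
    """Fuse decisions from non-overlapping epochs by summing decision values.

    The fused prediction is the sign of ``Σ f_i`` and the fused posterior
    is the logistic of the summed decision value.
    """
    fs = [d.f if isinstance(d, TrialDecision) else float(d) for d in decisions]
    f = float(np.sum(fs))
    return TrialDecision(f=f, predicted="+" if f > 0 else "-",
                         posterior=float(_sigmoid(np.array(f))))


def multi_trial_accuracy(decisions: np.ndarray, labels: np.ndarray, k: int,
                         seed: int = 0, n_groups: int | None = None) -> float:
    """Accuracy of k-trial fused predictions over same-class groups.

    Groups of ``k`` decision values are drawn (without replacement within
    a group) from trials of the same class; each group's fused sign is
    compared with the class.  With ``n_groups=None`` the trials of each
    class are split into ⌊n/k⌋ disjoint consecutive groups; otherwise
    groups are resampled ``n_groups`` times for a Monte-Carlo estimate.
    """
    decisions = np.asarray(decisions, dtype=float)
    labels = np.where(np.asarray(labels) > 0, 1, -1)
    rng = np.random.default_rng(seed)
    correct, total = 0, 0
    for cls in (-1, 1):
        f_cls = decisions[labels == cls]
        if len(f_cls) < k:
            continue
        if n_groups is None:
            order = rng.permutation(len(f_cls))
            groups = [
                order[i * k:(i + 1) * k] for i in range(len(f_cls) // k)
            ]
        else:
            groups = [
                rng.choice(len(f_cls), size=k, replace=False)
                for _ in range(n_groups)
            ]
        for g in groups:
            fused = f_cls[g].sum()
            pred = 1 if fused > 0 else -1
            correct += int(pred == cls)
            total += 1
    if total == 0:
        raise ValueError("not enough trials for any group of size k")
    return correct / total


# --------------------------------------------------------------------------
# Generalization and learning curves
# --------------------------------------------------------------------------

def generalization_eval(partitions: dict, plan,
                        cfg: TrainConfig | None = None,
                        c: float = 1.0) -> dict:
    """Train/test across disjoint partitions (blocks, sessions, subjects).

    Parameters
    ----------
    partitions : dict
        Maps a unit key (e.g. ``("subj", 3)`` or ``"block1"``) to an
        :class:`EpochSet` or ``(X, y)`` tuple.
    plan : list of (train_keys, test_keys)
        Each entry trains one model on the concatenated train partitions
        and evaluates it on each test partition separately.  Train and
        test keys must be disjoint.

    Returns
    -------
    dict mapping (train_keys, test_key) -> {"rate": float, "decisions": array}
    """
    cfg = cfg or TrainConfig()

    def xy(key):
        part = partitions[key]
        if isinstance(part, EpochSet):
            fm = vectorize(part)
            return fm.X, fm.y
        return np.asarray(part[0]), np.asarray(part[1])

    out = {}
    for train_keys, test_keys in plan:
        train_keys, test_keys = tuple(train_keys), tuple(test_keys)
        if set(train_keys) & set(test_keys):
            raise ValueError(
                f"train/test partitions overlap: {set(train_keys) & set(test_keys)}"
            )
        Xs, ys = zip(*(xy(k) for k in train_keys))
        model = MismatchDecoder(np.concatenate(Xs), np.concatenate(ys)).fit(
            c, tol=cfg.tol, max_iter=cfg.max_iter
        )
        for tk in test_keys:
            Xt, yt = xy(tk)
            f = model.decision_value(Xt)
            pred = np.where(f > 0, 1, -1)
            out[(train_keys, tk)] = {
                "rate": float(np.mean(pred == yt)),
                "decisions": f,
            }
    return out


def leave_one_out_plan(keys) -> list:
    """One entry per key: train on all others, test on it."""
    keys = list(keys)
    return [
        ([k for k in keys if k != held_out], [held_out]) for held_out in keys
    ]


def learning_curve(epochs_or_xy, increments,
                   cfg: TrainConfig | None = None,
                   c: float = 1.0) -> np.ndarray:
    """CV rate using the first N trials for each N (collection order kept)."""
    cfg = cfg or TrainConfig()
    if isinstance(epochs_or_xy, EpochSet):
        fm = vectorize(epochs_or_xy)
        X, y = fm.X, fm.y
    else:
        X, y = epochs_or_xy
    rates = []
    for n in increments:
        if n < 2 * cfg.folds:
            raise ValueError(
                f"increment {n} is below 2x the fold count ({cfg.folds})"
            )
        if n > len(y):
            raise ValueError(f"increment {n} exceeds available trials")
        rates.append(cross_validate(X[:n], y[:n], cfg, c=c).mean_rate)
    return np.asarray(rates)
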