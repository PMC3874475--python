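"""Online probabilistic tracking of mismatch responses.

A trained decoder is applied to a stream of preprocessed epochs; decision
values are buffered in non-overlapping groups of ``k`` trials and, every
``k`` consumed epochs, the tracker emits the logistic of the summed
decision values — a posterior-probability index of deviance suitable for
neurofeedback.  Offline, the same decision values support decision-sorted
ERP grouping (quartile plots) and outcome grouping (hits / misses /
true negatives / false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet, is_deviant
from .decode import DecoderResults, TrialDecision, _sigmoid

__all__ = ["Tracker", "sort_by_decision", "outcome_groups"]


@dataclass
class Tracker:
    """Streaming posterior emitter over non-overlapping trial groups.

    ``group_size`` k of 1, 3, 5 or 10 are typical: larger groups stabilize
    the output but reduce the prediction rate (150 consumed trials at
    k=10 yield only 15 emissions).  ``fusion`` is ``"sum"`` (default,
    posterior of the summed decision value) or ``"mean"``.
    """

    model: DecoderResults
    group_size: int = 1
    fusion: str = "sum"
    _buffer: list = field(default_factory=list, repr=False)
    #: emitted (trial_index, fused_f, posterior, prediction) tuples
    emissions: list = field(default_factory=list, repr=False)
    _consumed: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if self.fusion not in ("sum", "mean"):
            raise ValueError("fusion must be 'sum' or 'mean'")

    def update(self, x: np.ndarray) -> TrialDecision | None:
        """Consume one epoch's feature vector; emit when the group is full."""
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != len(self.model.w):
            raise ValueError(
                f"epoch has {x.shape[0]} features but the model fingerprint "
                f"expects {len(self.model.w)}"
            )
        self._buffer.append(float(self.model.decision_value(x)))
        self._consumed += 1
        if len(self._buffer) < self.group_size:
            return None
        fs = np.array(self._buffer)
        self._buffer.clear()
        fused = float(fs.sum() if self.fusion == "sum" else fs.mean())
        decision = TrialDecision(
            f=fused, predicted="+" if fused > 0 else "-",
            posterior=float(_sigmoid(np.array(fused))),
        )
        self.emissions.append(
            (self._consumed - 1, decision.f, decision.posterior,
             decision.predicted)
        )
        return decision

    def run(self, epochs: EpochSet) -> list[TrialDecision]:
        """Stream a recorded epoch set; returns one decision per emission."""
        if self.model.fingerprint is not None:
            fp = self.model.fingerprint
            if (epochs.m, epochs.n) != (fp["m"], fp["n"]):
                raise ValueError(
                    f"epoch layout {(epochs.m, epochs.n)} does not match the "
                    f"model fingerprint {(fp['m'], fp['n'])}"
                )
        out = []
        for i in range(epochs.n_epochs):
            d = self.update(epochs.data[i].ravel())
            if d is not None:
                out.append(d)
        return out


def sort_by_decision(decisions, epochs: EpochSet, n_groups: int = 4
                     ) -> list[dict]:
    """Decision-sorted ERP grouping (quartiles by default).

    Trials are sorted ascending by decision value and split into
    ``n_groups`` contiguous groups (remainders spread over the last
    groups); each group's average ERP tracks the graded expression of the
    class-relevant components.
    """
    fs = np.array(
        [d.f if isinstance(d, TrialDecision) else float(d) for d in decisions]
    )
    if len(fs) != epochs.n_epochs:
        raise ValueError("one decision per epoch required")
    order = np.argsort(fs, kind="stable")
    base, extra = divmod(len(fs), n_groups)
    sizes = [base + (1 if g >= n_groups - extra else 0) for g in range(n_groups)]
    groups, start = [], 0
    for size in sizes:
        idx = order[start:start + size]
        start += size
        groups.append({
            "indices": idx,
            "mean_f": float(fs[idx].mean()) if size else np.nan,
            "erp": epochs.data[idx].mean(axis=0) if size else None,
        })
    return groups


def outcome_groups(decisions, labels, epochs: EpochSet) -> dict:
    """Group trials by signal-detection outcome; deviant is the target.

    Returns ``{"hit", "miss", "true_negative", "false_positive"}`` each
    with trial indices and the group-average ERP.  Group sizes sum to the
    trial count.
    """
    fs = np.array(
        [d.f if isinstance(d, TrialDecision) else float(d) for d in decisions]
    )
    labels = np.asarray(labels)
    if not (len(fs) == len(labels) == epochs.n_epochs):
        raise ValueError("decisions, labels and epochs must align")
    deviant = np.array([is_deviant(str(l)) or str(l) in ("+", "1") for l in labels])
    pred_pos = fs > 0
    masks = {
        "hit": deviant & pred_pos,
        "miss": deviant & ~pred_pos,
        "true_negative": ~deviant & ~pred_pos,
        "false_positive": ~deviant & pred_pos,
    }
    out = {}
    for name, mask in masks.items():
        idx = np.flatnonzero(mask)
        out[name] = {
            "indices": idx,
            "erp": epochs.data[idx].mean(axis=0) if len(idx) else None,
        }
    return out
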