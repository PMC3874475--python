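"""Core data containers: continuous recordings, epoch sets, feature matrices.

The decoding problem treats each trial as an ``m × n`` matrix of ``m``
channels by ``n`` samples; classifiers operate on its vectorized form.
Containers here carry the bookkeeping (time axes, labels, montage,
preprocessing provenance) that keeps those transformations reversible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage

__all__ = [
    "Event",
    "Recording",
    "EpochSet",
    "FeatureMatrix",
    "STANDARD",
    "DEVIANT_PREFIX",
    "extract_epochs",
    "select_balanced_oddball",
    "vectorize",
    "devectorize",
]

#: Event/epoch label for the frequent (negative-class) trials.
STANDARD = "standard"
#: Deviant labels are ``deviant`` or ``deviant:<subtype>``.
DEVIANT_PREFIX = "deviant"


def is_deviant(label: str) -> bool:
    return label == DEVIANT_PREFIX or label.startswith(DEVIANT_PREFIX + ":")


@dataclass(frozen=True)
class Event:
    sample: int
    label: str


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts with stimulus events."""

    sample_rate: float
    signal: np.ndarray  # (channels, samples), μV
    montage: Montage
    events: list[Event]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.signal.shape[0] != len(self.montage):
            raise ValueError(
                f"signal has {self.signal.shape[0]} channels but montage has "
                f"{len(self.montage)}"
            )
        self.events = sorted(
            (Event(int(e.sample), str(e.label)) for e in self.events),
            key=lambda e: e.sample,
        )
        samples = [e.sample for e in self.events]
        if len(set(samples)) != len(samples):
            raise ValueError("event sample indices must be strictly increasing")
        if self.events and (
            self.events[0].sample < 0
            or self.events[-1].sample >= self.signal.shape[1]
        ):
            raise ValueError("event sample indices must lie within the signal")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class EpochSet:
    """Epochs × channels × samples with labels and a uniform time axis.

    ``times`` are milliseconds relative to stimulus onset; spacing is
    exactly ``1000 / sample_rate``.  ``labels`` keep the full event label
    (``standard`` / ``deviant:<subtype>``); class membership is derived.
    """

    data: np.ndarray  # (epochs, m, n), μV
    labels: np.ndarray  # (epochs,) str
    times: np.ndarray  # (n,) ms
    sample_rate: float
    montage: Montage
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels length must equal epoch count")
        if self.data.shape[2] != len(self.times):
            raise ValueError("times length must equal sample count")
        if self.data.shape[1] != len(self.montage):
            raise ValueError("channel count must match montage size")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1000.0 / self.sample_rate, atol=1e-6):
                raise ValueError(
                    "times must be uniform with spacing 1000/sample_rate ms"
                )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        """Number of channels."""
        return self.data.shape[1]

    @property
    def n(self) -> int:
        """Number of samples per epoch."""
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Per-epoch class sign: ``+`` for deviant, ``−`` for standard."""
        return np.array(
            ["+" if is_deviant(l) else "-" for l in self.labels], dtype=object
        )

    @property
    def y(self) -> np.ndarray:
        """Numeric class labels: +1 deviant, −1 standard."""
        return np.array([1 if is_deviant(l) else -1 for l in self.labels])

    def select_epochs(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx], labels=self.labels[idx])

    def select_channels(self, idx) -> "EpochSet":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self, data=self.data[:, idx], montage=self.montage.subset(idx)
        )

    def with_provenance(self, **kv) -> "EpochSet":
        prov = dict(self.provenance)
        prov.update(kv)
        return replace(self, provenance=prov)


@dataclass
class FeatureMatrix:
    """Vectorized epochs: one row per epoch, ``m·n`` columns.

    The layout is channel-major: all time points of channel 0, then
    channel 1, and so on.  ``layout`` maps a column index to its
    ``(channel, time)`` origin, and the fingerprint identifies the layout
    so trained weights are portable across compatible data.
    """

    X: np.ndarray  # (epochs, m*n)
    y: np.ndarray  # (epochs,) in {-1, +1}
    m: int
    n: int
    channel_labels: tuple[str, ...]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[1] != self.m * self.n:
            raise ValueError("column count must equal m*n")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column_of(self, channel: int, time_index: int) -> int:
        return channel * self.n + time_index

    def origin_of(self, column: int) -> tuple[int, int]:
        return divmod(column, self.n)

    @property
    def fingerprint(self) -> dict:
        """Feature-layout identity stored with trained models."""
        return {
            "order": "channel-major",
            "m": self.m,
            "n": self.n,
            "channels": list(self.channel_labels),
            "times_ms": [round(float(t), 6) for t in self.times],
        }


def _window_sample_range(
    window_ms: tuple[float, float], sample_rate: float
) -> np.ndarray:
    """Sample offsets (relative to the event sample) covering the window.

    The window is half-open ``[start, end)`` on the sample grid anchored at
    stimulus onset: offsets ``k`` with ``start <= k/fs*1000 < end``.  At
    256 Hz a (−50, 450) ms window therefore yields exactly 128 samples.
    """
    start, end = window_ms
    lo = int(np.ceil(start * sample_rate / 1000.0 - 1e-9))
    hi = int(np.ceil(end * sample_rate / 1000.0 - 1e-9))  # exclusive
    return np.arange(lo, hi)


def extract_epochs(rec: Recording, window_ms: tuple[float, float]) -> EpochSet:
    """Cut one epoch per event from a continuous recording.

    Events whose window would extend beyond the recording bounds are
    skipped with a warning rather than zero-padded.
    """
    start, end = window_ms
    if not start < end:
        raise ValueError("window start must be before end")
    offsets = _window_sample_range(window_ms, rec.sample_rate)
    if len(offsets) == 0:
        raise ValueError("window contains no samples at this rate")
    n_total = rec.n_samples
    data, labels = [], []
    skipped = []
    for ev in rec.events:
        lo, hi = ev.sample + offsets[0], ev.sample + offsets[-1]
        if lo < 0 or hi >= n_total:
            skipped.append(ev.sample)
            continue
        data.append(rec.signal[:, ev.sample + offsets])
        labels.append(ev.label)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} event(s) whose epoch window exceeds the "
            f"recording bounds (first at sample {skipped[0]})",
            stacklevel=2,
        )
    if not data:
        raise ValueError("no events remain after windowing")
    times = offsets * 1000.0 / rec.sample_rate
    return EpochSet(
        data=np.stack(data),
        labels=np.array(labels, dtype=object),
        times=times,
        sample_rate=rec.sample_rate,
        montage=rec.montage,
        provenance={
            "window_ms": [float(start), float(end)],
            "source_meta": dict(rec.meta),
        },
    )


def select_balanced_oddball(epochs: EpochSet) -> EpochSet:
    """Balance classes by pairing each deviant with its preceding standard.

    Keeps every deviant epoch and exactly the standard epoch immediately
    preceding it in sequence order, discarding all other standards — the
    selection used to equalize class counts in oddball blocks.
    """
    labels = epochs.labels
    keep: list[int] = []
    for i, lab in enumerate(labels):
        if is_deviant(lab):
            if i > 0 and not is_deviant(labels[i - 1]):
                keep.extend([i - 1, i])
    if not any(is_deviant(l) for l in labels):
        warnings.warn("no deviant epochs present; returning empty set",
                      stacklevel=2)
        return epochs.select_epochs(np.array([], dtype=int))
    out = epochs.select_epochs(np.array(sorted(set(keep)), dtype=int))
    return out.with_provenance(balanced="preceding-standard")


def vectorize(epochs: EpochSet) -> FeatureMatrix:
    """Flatten epochs to a feature matrix in channel-major order."""
    n_ep = epochs.n_epochs
    X = epochs.data.reshape(n_ep, epochs.m * epochs.n)
    return FeatureMatrix(
        X=X,
        y=epochs.y,
        m=epochs.m,
        n=epochs.n,
        channel_labels=epochs.montage.labels,
        times=epochs.times.copy(),
    )


def devectorize(fm: FeatureMatrix, montage: Montage,
                sample_rate: float) -> EpochSet:
    """Exact inverse of :func:`vectorize`."""
    data = fm.X.reshape(fm.X.shape[0], fm.m, fm.n)
    labels = np.array(
        [DEVIANT_PREFIX if yi > 0 else STANDARD for yi in fm.y], dtype=object
    )
    return EpochSet(
        data=data,
        labels=labels,
        times=fm.times.copy(),
        sample_rate=sample_rate,
        montage=montage,
    )
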