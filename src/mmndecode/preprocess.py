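"""Optimized preprocessing chain for single-trial mismatch decoding.

Stage order (each optional, parameters configurable):

1. per-epoch bad-channel detection (DC offset / 50 Hz power) and
   spherical-spline repair,
2. ICA-based artifact removal with an automatic variance threshold,
3. zero-phase band-pass filtering (default 0.5–13 Hz),
4. baseline correction and ±75 μV epoch rejection,
5. re-referencing (mastoid average by default; CAR / surface Laplacian /
   none available),
6. cropping to the analysis window and anti-aliased resampling to 32 Hz,
   with a final baseline correction.

Epochs are initially cut wide (−200..600 ms) so the filter has padding
around the analysis window (−50..450 ms); the final crop discards the
edges.  Every stage appends a serializable entry to a
:class:`StageReport`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA

from .containers import EpochSet, Recording, extract_epochs
from .spline import interpolation_matrix, surface_laplacian

__all__ = [
    "PreprocConfig",
    "StageReport",
    "detect_bad_channels",
    "band_power_50hz",
    "repair_channels_spline",
    "ica_remove_artifacts",
    "bandpass",
    "baseline_correct",
    "reject_epochs",
    "rereference",
    "resample",
    "crop_epochs",
    "run_pipeline",
]


@dataclass(frozen=True)
class PreprocConfig:
    """Parameters of the preprocessing chain (defaults are the optimized set)."""

    epoch_window_ms: tuple[float, float] = (-200.0, 600.0)
    analysis_window_ms: tuple[float, float] = (-50.0, 450.0)
    baseline_window_ms: tuple[float, float] = (-50.0, 0.0)

    bad_channel_enabled: bool = True
    bad_channel_offset_mv: float = 35.0
    bad_channel_line_power_uv2: float = 1000.0

    ica_enabled: bool = True
    ica_threshold_factor: float = 1.0
    ica_seed: int = 0
    ica_max_iter: int = 500
    # The unmixing is estimated on at most this many time samples (a
    # deterministic stride through the concatenated epochs); components are
    # then applied to all samples.  Pure speed knob — the decomposition is
    # spatially fixed either way.
    ica_fit_max_samples: int = 20000

    filter_enabled: bool = True
    filter_low_hz: float = 0.5
    filter_high_hz: float = 13.0
    filter_order: int = 4

    reject_enabled: bool = True
    reject_threshold_uv: float = 75.0

    reference: str = "mastoid"  # mastoid | CAR | laplacian | none

    resample_to_hz: float = 32.0

    def validate(self, sample_rate: float) -> None:
        nyq = sample_rate / 2.0
        if self.filter_enabled and not (
            0 < self.filter_low_hz < self.filter_high_hz < nyq
        ):
            raise ValueError(
                f"filter cutoffs must satisfy 0 < low < high < Nyquist ({nyq})"
            )
        if self.reference not in ("mastoid", "CAR", "laplacian", "none"):
            raise ValueError(f"unknown reference scheme {self.reference!r}")

    _FLAT_KEYS = {
        "epoch.window_ms": "epoch_window_ms",
        "epoch.analysis_window_ms": "analysis_window_ms",
        "epoch.baseline_window_ms": "baseline_window_ms",
        "bad_channel.enabled": "bad_channel_enabled",
        "bad_channel.offset_mv": "bad_channel_offset_mv",
        "bad_channel.line_power_uv2": "bad_channel_line_power_uv2",
        "ica.enabled": "ica_enabled",
        "ica.threshold_factor": "ica_threshold_factor",
        "ica.seed": "ica_seed",
        "ica.max_iter": "ica_max_iter",
        "filter.enabled": "filter_enabled",
        "filter.low_hz": "filter_low_hz",
        "filter.high_hz": "filter_high_hz",
        "filter.order": "filter_order",
        "reject.enabled": "reject_enabled",
        "reject.threshold_uv": "reject_threshold_uv",
        "reference.scheme": "reference",
        "resample.to_hz": "resample_to_hz",
    }

    @classmethod
    def from_flat(cls, flat: dict) -> "PreprocConfig":
        """Build from a flat ``stage.parameter`` mapping; unknown keys reject."""
        kwargs = {}
        for key, value in flat.items():
            if key not in cls._FLAT_KEYS:
                raise KeyError(f"unknown preprocessing config key: {key}")
            name = cls._FLAT_KEYS[key]
            if name.endswith("_ms") and isinstance(value, (list, tuple)):
                value = tuple(float(v) for v in value)
            kwargs[name] = value
        return cls(**kwargs)


@dataclass
class StageReport:
    """Per-stage record of what the pipeline did."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, **info})

    def to_json(self, **kw) -> str:
        return json.dumps(self.stages, default=_jsonable, **kw)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not serializable: {type(obj)}")


# --------------------------------------------------------------------------
# Bad channels
# --------------------------------------------------------------------------

def band_power_50hz(x: np.ndarray, sample_rate: float,
                    line_freq: float = 50.0, half_band: float = 1.0
                    ) -> np.ndarray:
    """Line-band power (μV²) along the last axis.

    Estimator: averaged (Welch) periodogram with a boxcar window of up to
    one second (≈1 Hz resolution), power integrated over
    ``line_freq ± half_band``.  For a pure on-bin sinusoid of amplitude A
    this integrates to its mean-square power A²/2.
    """
    n = x.shape[-1]
    nperseg = min(n, int(round(sample_rate)))
    freqs, psd = sps.welch(
        x, fs=sample_rate, window="boxcar", nperseg=nperseg, noverlap=0,
        detrend="constant", scaling="density", axis=-1,
    )
    df = freqs[1] - freqs[0]
    mask = (freqs >= line_freq - half_band) & (freqs <= line_freq + half_band)
    return psd[..., mask].sum(axis=-1) * df


def detect_bad_channels(epochs: EpochSet, cfg: PreprocConfig
                        ) -> list[np.ndarray]:
    """Flag scalp channels per epoch by DC offset or 50 Hz line power.

    A channel is bad within an epoch if its absolute mean amplitude
    exceeds the offset threshold (mV) or its estimated 50 Hz band power
    exceeds the power threshold (μV²).
    """
    if epochs.sample_rate <= 100:
        raise ValueError("sample rate must exceed 100 Hz to resolve 50 Hz")
    eeg = epochs.montage.eeg_indices
    data = epochs.data[:, eeg, :]  # (epochs, n_eeg, n)
    offsets_uv = np.abs(data.mean(axis=2))
    line = band_power_50hz(data, epochs.sample_rate)
    bad = (offsets_uv > cfg.bad_channel_offset_mv * 1000.0) | (
        line > cfg.bad_channel_line_power_uv2
    )
    return [eeg[np.flatnonzero(bad[i])] for i in range(epochs.n_epochs)]


def repair_channels_spline(epochs: EpochSet, bad_lists) -> EpochSet:
    """Replace flagged channels by their spherical-spline estimate.

    Interpolation uses the remaining good scalp electrodes of the same
    epoch; at least 4 good channels must remain.
    """
    eeg = set(epochs.montage.eeg_indices.tolist())
    data = epochs.data.copy()
    pos = epochs.montage.positions
    cache: dict[tuple, np.ndarray] = {}
    for ep, bad in enumerate(bad_lists):
        bad = tuple(sorted(int(b) for b in bad))
        if not bad:
            continue
        good = sorted(eeg - set(bad))
        if len(good) < 4:
            raise ValueError(
                f"epoch {ep}: only {len(good)} good channels remain"
            )
        if bad not in cache:
            cache[bad] = interpolation_matrix(pos[good], pos[list(bad)])
        data[ep, list(bad), :] = cache[bad] @ data[ep, good, :]
    return replace(epochs, data=data).with_provenance(repaired=True)


# --------------------------------------------------------------------------
# ICA artifact removal
# --------------------------------------------------------------------------

def ica_remove_artifacts(
    epochs: EpochSet, cfg: PreprocConfig | None = None,
    remove: list[int] | None = None,
) -> tuple[EpochSet, dict]:
    """Decompose into spatially fixed components and drop high-variance ones.

    The decomposition is a linear ICA fitted on the concatenated epochs.
    Each component's artifact score is the mean across trials of the
    variance of its back-projected contribution to the channel data; the
    removal threshold is the grand mean of the scores over components
    (times ``ica_threshold_factor``).  Eye blinks and similar artifacts
    concentrate large variance in few components and exceed the mean.

    ``remove`` overrides the automatic selection (an empty list makes the
    operation a numerical identity: all components are re-projected).
    """
    cfg = cfg or PreprocConfig()
    n_ep, m, n = epochs.data.shape
    if n_ep * n < m:
        raise ValueError("too few samples for ICA decomposition")
    X = epochs.data.transpose(0, 2, 1).reshape(n_ep * n, m)
    stride = max(1, int(np.ceil(len(X) / cfg.ica_fit_max_samples)))
    X_fit = X[::stride]
    rank = np.linalg.matrix_rank(
        X_fit - X_fit.mean(0), tol=1e-8 * max(X_fit.shape)
    )
    k = min(m, rank)
    ica = FastICA(
        n_components=k, whiten="unit-variance", random_state=cfg.ica_seed,
        max_iter=cfg.ica_max_iter, tol=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings surface below
        ica.fit(X_fit)
        S = ica.transform(X)  # (N, k)
    if ica.n_iter_ >= cfg.ica_max_iter:
        warnings.warn(
            f"ICA did not fully converge in {ica.n_iter_} iterations",
            stacklevel=2,
        )
    mixing = ica.mixing_  # (m, k)

    # Per-component artifact scores on the back-projected contributions.
    S_ep = S.reshape(n_ep, n, k)
    gain = np.sum(mixing**2, axis=0)  # channel-space energy per component
    per_trial_var = S_ep.var(axis=1) * gain[None, :]  # (n_ep, k)
    scores = per_trial_var.mean(axis=0)
    threshold = cfg.ica_threshold_factor * scores.mean()
    if remove is None:
        remove = np.flatnonzero(scores > threshold).tolist()

    keep = np.setdiff1d(np.arange(k), np.asarray(remove, dtype=int))
    X_clean = S[:, keep] @ mixing[:, keep].T + ica.mean_
    data = X_clean.reshape(n_ep, n, m).transpose(0, 2, 1)
    report = {
        "n_components": int(k),
        "removed": [int(r) for r in remove],
        "scores": scores.tolist(),
        "threshold": float(threshold),
    }
    out = replace(epochs, data=data).with_provenance(ica_removed=report["removed"])
    return out, report


# --------------------------------------------------------------------------
# Filtering / resampling / referencing
# --------------------------------------------------------------------------

def _butter_sos(low: float, high: float, fs: float, order: int):
    nyq = fs / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    if not 0 < low < high:
        raise ValueError("cutoffs must satisfy 0 < low < high")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(obj, low: float, high: float, order: int = 4):
    """Zero-phase Butterworth band-pass (forward-backward) in μV.

    Works on a :class:`Recording` (continuous) or an :class:`EpochSet`
    (each epoch filtered along time).  The default band (0.5–13 Hz at
    256 Hz) attenuates 50 Hz line noise by more than 40 dB while staying
    within 1 dB in the passband midrange.
    """
    if isinstance(obj, Recording):
        sos = _butter_sos(low, high, obj.sample_rate, order)
        padlen = _filtfilt_padlen(obj.sample_rate, low, obj.n_samples)
        out = sps.sosfiltfilt(sos, obj.signal, axis=1, padlen=padlen)
        return Recording(obj.sample_rate, out, obj.montage, obj.events,
                         dict(obj.meta))
    sos = _butter_sos(low, high, obj.sample_rate, order)
    padlen = _filtfilt_padlen(obj.sample_rate, low, obj.n)
    data = sps.sosfiltfilt(sos, obj.data, axis=2, padlen=padlen)
    return replace(obj, data=data).with_provenance(bandpass=[low, high])


def _filtfilt_padlen(fs: float, low: float, n: int) -> int:
    # The high-pass corner dominates the impulse-response length; pad a
    # few of its time constants so edge transients stay out of the data.
    return int(min(n - 1, max(24, 3 * fs / low)))


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float] = (-50.0, 0.0)
                     ) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    start, end = window_ms
    mask = (epochs.times >= start - 1e-9) & (epochs.times <= end + 1e-9)
    if not mask.any():
        raise ValueError(
            f"baseline window {window_ms} contains no samples of the epoch"
        )
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def reject_epochs(epochs: EpochSet, threshold_uv: float = 75.0
                  ) -> tuple[EpochSet, np.ndarray]:
    """Drop epochs whose scalp-EEG amplitude exceeds ``±threshold_uv``.

    Only ``eeg``-role channels are inspected; large EOG excursions alone
    do not reject an epoch.  Assumes baseline correction was applied.
    """
    eeg = epochs.montage.eeg_indices
    peak = np.abs(epochs.data[:, eeg, :]).max(axis=(1, 2))
    rejected = np.flatnonzero(peak > threshold_uv)
    kept = np.setdiff1d(np.arange(epochs.n_epochs), rejected)
    if len(kept) == 0:
        warnings.warn("all epochs rejected", stacklevel=2)
    out = epochs.select_epochs(kept).with_provenance(
        rejected=[int(r) for r in rejected]
    )
    return out, rejected


def rereference(epochs: EpochSet, scheme: str = "mastoid") -> EpochSet:
    """Re-reference scalp data.

    ``mastoid``: subtract the mean of the two mastoid leads from every
    EEG and mastoid channel per sample.  ``CAR``: subtract the per-sample
    mean over EEG channels from the EEG channels.  ``laplacian``:
    replace EEG channels by their spherical-spline surface Laplacian.
    ``none``: identity.
    """
    if scheme == "none":
        return epochs
    data = epochs.data.copy()
    eeg = epochs.montage.eeg_indices
    if scheme == "mastoid":
        mast = epochs.montage.role_indices("mastoid")
        if len(mast) != 2:
            raise ValueError("mastoid referencing requires exactly 2 mastoids")
        ref = data[:, mast, :].mean(axis=1, keepdims=True)
        chans = np.concatenate([eeg, mast])
        data[:, chans, :] -= ref
    elif scheme == "CAR":
        ref = data[:, eeg, :].mean(axis=1, keepdims=True)
        data[:, eeg, :] -= ref
    elif scheme == "laplacian":
        L = surface_laplacian(epochs.montage.positions[eeg])
        data[:, eeg, :] = np.einsum("ij,ejn->ein", L, data[:, eeg, :])
    else:
        raise ValueError(f"unknown reference scheme {scheme!r}")
    return replace(epochs, data=data).with_provenance(reference=scheme)


def resample(epochs: EpochSet, target_hz: float,
             band_high_hz: float | None = None) -> EpochSet:
    """Anti-aliased polyphase resampling along the time axis."""
    if band_high_hz is not None and target_hz < 2 * band_high_hz:
        raise ValueError(
            f"target {target_hz} Hz violates Nyquist for the {band_high_hz} Hz band"
        )
    if abs(target_hz - epochs.sample_rate) < 1e-9:
        return epochs
    frac = Fraction(target_hz / epochs.sample_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = sps.resample_poly(epochs.data, up, down, axis=2)
    n_new = data.shape[2]
    times = epochs.times[0] + np.arange(n_new) * 1000.0 / target_hz
    return EpochSet(
        data=data, labels=epochs.labels.copy(), times=times,
        sample_rate=target_hz, montage=epochs.montage,
        provenance={**epochs.provenance, "resampled_to": target_hz},
    )


def crop_epochs(epochs: EpochSet, window_ms: tuple[float, float]) -> EpochSet:
    """Keep samples in the half-open window [start, end) on the time grid."""
    start, end = window_ms
    mask = (epochs.times >= start - 1e-9) & (epochs.times < end - 1e-9)
    if not mask.any():
        raise ValueError(f"crop window {window_ms} is empty")
    return EpochSet(
        data=epochs.data[:, :, mask], labels=epochs.labels.copy(),
        times=epochs.times[mask], sample_rate=epochs.sample_rate,
        montage=epochs.montage,
        provenance={**epochs.provenance, "window_ms": list(window_ms)},
    )


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

def run_pipeline(rec: Recording, cfg: PreprocConfig | None = None
                 ) -> tuple[EpochSet, StageReport]:
    """Apply the full chain to a continuous recording.

    Repair → ICA → filter → baseline → rejection → re-reference → crop →
    resample → baseline.  Filtering happens on the wide epochs so the
    final analysis window is padded against edge effects.
    """
    cfg = cfg or PreprocConfig()
    cfg.validate(rec.sample_rate)
    report = StageReport()

    epochs = extract_epochs(rec, cfg.epoch_window_ms)
    report.add("epoch", window_ms=list(cfg.epoch_window_ms),
               n_epochs=epochs.n_epochs)

    if cfg.bad_channel_enabled:
        bad_lists = detect_bad_channels(epochs, cfg)
        n_flagged = int(sum(len(b) > 0 for b in bad_lists))
        epochs = repair_channels_spline(epochs, bad_lists)
        report.add(
            "bad_channel_repair",
            offset_mv=cfg.bad_channel_offset_mv,
            line_power_uv2=cfg.bad_channel_line_power_uv2,
            epochs_with_repairs=n_flagged,
            repaired={
                str(i): [epochs.montage.labels[c] for c in b]
                for i, b in enumerate(bad_lists) if len(b)
            },
        )

    if cfg.ica_enabled:
        epochs, ica_report = ica_remove_artifacts(epochs, cfg)
        report.add("ica", **ica_report)

    if cfg.filter_enabled:
        epochs = bandpass(epochs, cfg.filter_low_hz, cfg.filter_high_hz,
                          cfg.filter_order)
        report.add("filter", low_hz=cfg.filter_low_hz,
                   high_hz=cfg.filter_high_hz, order=cfg.filter_order)

    epochs = baseline_correct(epochs, cfg.baseline_window_ms)

    if cfg.reject_enabled:
        epochs, rejected = reject_epochs(epochs, cfg.reject_threshold_uv)
        report.add("reject", threshold_uv=cfg.reject_threshold_uv,
                   rejected=[int(r) for r in rejected])

    epochs = rereference(epochs, cfg.reference)
    report.add("reference", scheme=cfg.reference)

    epochs = crop_epochs(epochs, cfg.analysis_window_ms)
    if cfg.resample_to_hz and cfg.resample_to_hz != rec.sample_rate:
        epochs = resample(
            epochs, cfg.resample_to_hz,
            band_high_hz=cfg.filter_high_hz if cfg.filter_enabled else None,
        )
        report.add("resample", to_hz=cfg.resample_to_hz,
                   n_samples=epochs.n)
    epochs = baseline_correct(epochs, cfg.baseline_window_ms)
    report.add("baseline", window_ms=list(cfg.baseline_window_ms))
    return epochs, report
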