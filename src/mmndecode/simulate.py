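"""Synthetic oddball-EEG generator.

Emulates 64-channel recordings of auditory mismatch paradigms so the whole
decoding chain can be exercised without real data: ERP components (N1 on
both trial types, an extra mismatch negativity and a P3a on deviants) are
rendered as Gaussian-in-time bumps with fronto-central scalp topographies,
superimposed on 1/f background noise, 50 Hz line interference, ocular
blink transients, optional bad channels, and multiplicative per-trial
habituation.  Every random element is driven by a single seed.

Default amplitudes and timings follow the classical morphology of mismatch
responses to simple tone contrasts: an N1 near 100 ms, a deviant-only
negativity peaking ~150 ms over fronto-central sites (1–5 μV against
ongoing EEG that can exceed ±30 μV), and a deviant-only positivity near
300 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import DEVIANT_PREFIX, STANDARD, Event, Recording
from .montage import FRONTOCENTRAL_9, Montage, make_standard_montage

__all__ = [
    "ParadigmSpec",
    "ComponentTemplate",
    "SimConfig",
    "generate_sequence",
    "render_recording",
    "simulate_recording",
    "ground_truth",
    "default_templates",
]

#: Default subtypes for the multi-deviant ("optimal") paradigm.
OPTIMAL_DEVIANT_TYPES = ("location", "frequency", "amplitude", "duration", "gap")


@dataclass(frozen=True)
class ParadigmSpec:
    """Stimulus-sequence design.

    ``oddball``: frequent standards with rare, isolated deviants (default
    15% deviants, 1000 trials/block).  ``optimal``: strict alternation of
    standards with deviants drawn from up to five subtypes (default 600
    trials/block, five subtypes at 10% each).
    """

    kind: str = "oddball"
    n_trials: int = 1000
    deviant_proportion: float = 0.15
    deviant_types: tuple[tuple[str, float], ...] = tuple(
        (t, 0.10) for t in OPTIMAL_DEVIANT_TYPES
    )
    isi_ms: float = 500.0
    no_adjacent_deviants: bool = True
    exact_counts: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("oddball", "optimal"):
            raise ValueError(f"unknown paradigm kind {self.kind!r}")
        if self.kind == "oddball":
            if not 0 <= self.deviant_proportion <= 1:
                raise ValueError("deviant_proportion must be in [0, 1]")
            k = self.deviant_proportion * self.n_trials
            if self.exact_counts and abs(k - round(k)) > 1e-9:
                raise ValueError(
                    "n_trials x deviant_proportion must be an integer in "
                    "exact-count mode"
                )
        else:
            total = sum(p for _, p in self.deviant_types)
            if total > 0.5 + 1e-9:
                raise ValueError(
                    "optimal paradigm needs deviant proportions summing to <=0.5"
                )
            for _, p in self.deviant_types:
                k = p * self.n_trials
                if self.exact_counts and abs(k - round(k)) > 1e-9:
                    raise ValueError(
                        "per-type trial counts must be integers in "
                        "exact-count mode"
                    )


@dataclass(frozen=True)
class ComponentTemplate:
    """One ERP component rendered as a Gaussian bump in time.

    ``half_width_ms`` is the full width at half maximum; ``amplitude_uv``
    carries the polarity; ``topography`` weights each montage channel in
    [−1, 1]; ``habituation_rate`` r scales the amplitude by ``(1−r)^t``
    at trial index t; ``trial_jitter_sd`` is the SD of additive Gaussian
    amplitude jitter per trial (μV).
    """

    name: str
    peak_latency_ms: float
    half_width_ms: float
    amplitude_uv: float
    topography: np.ndarray
    classes_affected: tuple[str, ...] = (STANDARD, DEVIANT_PREFIX)
    trial_jitter_sd: float = 0.0
    habituation_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.half_width_ms <= 0:
            raise ValueError("half_width_ms must be positive")
        topo = np.asarray(self.topography, dtype=float)
        if np.any(np.abs(topo) > 1 + 1e-9):
            raise ValueError("topography weights must lie in [-1, 1]")
        object.__setattr__(self, "topography", topo)

    def affects(self, label: str) -> bool:
        if label == STANDARD:
            return STANDARD in self.classes_affected
        return DEVIANT_PREFIX in self.classes_affected


@dataclass(frozen=True)
class BadChannelSpec:
    label: str
    offset_uv: float = 40000.0  # 40 mV DC offset
    noise_rms_uv: float = 0.0
    line_amplitude_uv: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Recording-level simulation parameters (one seed fixes everything)."""

    seed: int = 0
    montage: Montage = field(default_factory=make_standard_montage)
    sample_rate: float = 256.0
    noise_exponent: float = 1.0  # 1/f^alpha background
    noise_rms_uv: float = 10.0
    line_freq_hz: float = 50.0
    line_amplitude_uv: float = 2.0
    blink_rate_hz: float = 0.1
    blink_amplitude_uv: float = 120.0
    blink_width_ms: float = 250.0
    bad_channels: tuple[BadChannelSpec, ...] = ()
    subject_latency_shift_sd_ms: float = 15.0
    subject_amplitude_scale_sd: float = 0.15
    blocks_per_session: int = 1
    sessions: int = 1
    pad_ms: float = 1000.0


def _gauss_topography(montage: Montage, center_label: str,
                      spread_deg: float = 55.0,
                      include_eog: bool = False) -> np.ndarray:
    """Unit-peak Gaussian falloff with great-circle angle from a channel."""
    pos = montage.positions
    c = pos[montage.index(center_label)]
    ang = np.degrees(np.arccos(np.clip(pos @ c, -1, 1)))
    topo = np.exp(-0.5 * (ang / spread_deg) ** 2)
    for i, role in enumerate(montage.roles):
        if role != "eeg" and not include_eog:
            topo[i] = 0.0
    return topo


def default_templates(montage: Montage) -> tuple[ComponentTemplate, ...]:
    """N1 (both classes), deviant-only MMN and P3a, fronto-centrally maximal."""
    fc = _gauss_topography(montage, "FCz")
    return (
        ComponentTemplate(
            name="N1", peak_latency_ms=100.0, half_width_ms=70.0,
            amplitude_uv=-2.0, topography=fc,
            classes_affected=(STANDARD, DEVIANT_PREFIX),
            trial_jitter_sd=0.5, habituation_rate=0.0,
        ),
        ComponentTemplate(
            name="MMN", peak_latency_ms=150.0, half_width_ms=100.0,
            amplitude_uv=-3.0, topography=fc,
            classes_affected=(DEVIANT_PREFIX,),
            trial_jitter_sd=1.0, habituation_rate=0.0005,
        ),
        ComponentTemplate(
            name="P3a", peak_latency_ms=300.0, half_width_ms=100.0,
            amplitude_uv=3.0, topography=fc,
            classes_affected=(DEVIANT_PREFIX,),
            trial_jitter_sd=1.0, habituation_rate=0.0005,
        ),
    )


def generate_sequence(
    spec: ParadigmSpec, seed: int | np.random.Generator = 0
) -> tuple[list[str], np.ndarray]:
    """Draw one block's trial labels and onset times.

    Returns ``(labels, onsets_ms)``.  Oddball blocks place exactly
    ``round(n_trials * deviant_proportion)`` deviants (exact-count mode),
    never at the first trial and — when ``no_adjacent_deviants`` — never
    adjacent, so every deviant has an immediately preceding standard.
    Optimal blocks strictly alternate standard/deviant with balanced,
    shuffled subtypes.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = spec.n_trials
    onsets = np.arange(n) * spec.isi_ms
    if spec.kind == "oddball":
        k = int(round(spec.deviant_proportion * n))
        labels = [STANDARD] * n
        slots = n - 1  # deviants allowed at trials 1..n-1
        if spec.no_adjacent_deviants:
            if k > (slots + 1) // 2:
                raise ValueError(
                    f"cannot place {k} non-adjacent deviants in {n} trials"
                )
            # Bijection between k-subsets without adjacency and plain
            # k-subsets of a reduced range.
            q = np.sort(rng.choice(slots - k + 1, size=k, replace=False))
            positions = q + np.arange(k) + 1
        else:
            if k > slots:
                raise ValueError("too many deviants")
            positions = rng.choice(np.arange(1, n), size=k, replace=False)
        for p in positions:
            labels[int(p)] = DEVIANT_PREFIX
    else:
        types = [t for t, _ in spec.deviant_types]
        counts = [int(round(p * n)) for _, p in spec.deviant_types]
        subtype_pool = [t for t, c in zip(types, counts) for _ in range(c)]
        rng.shuffle(subtype_pool)
        labels = []
        it = iter(subtype_pool)
        for i in range(n):
            if i % 2 == 0:
                labels.append(STANDARD)
            else:
                try:
                    labels.append(f"{DEVIANT_PREFIX}:{next(it)}")
                except StopIteration:
                    labels.append(STANDARD)
    return labels, onsets


def _one_over_f_noise(rng: np.random.Generator, n_channels: int,
                      n_samples: int, fs: float, exponent: float,
                      rms: float) -> np.ndarray:
    """Frequency-domain synthesis: amplitude ∝ f^(−α/2), random phases."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=(n_channels, len(freqs)))
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    cur = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    cur[cur == 0] = 1.0
    return x / cur * rms


def _blink_kernel(fs: float, width_ms: float) -> np.ndarray:
    """Smooth positive transient (squared half-sine), unit peak."""
    n = max(int(round(width_ms / 1000.0 * fs)), 3)
    t = np.linspace(0, np.pi, n)
    return np.sin(t) ** 2


def render_recording(
    sequence,
    onsets_ms: np.ndarray,
    templates,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    latency_shift_ms: float = 0.0,
    amplitude_scale: float = 1.0,
    meta: dict | None = None,
) -> Recording:
    """Render one block of continuous EEG from a trial sequence.

    Each trial adds, for every template affecting its class, a Gaussian
    bump ``A_t * topo * exp(-(t-peak)^2 / (2 sigma^2))`` with
    ``A_t = (amplitude + jitter) * (1 - habituation_rate)^t``; noise and
    artifacts are added on top.  ``latency_shift_ms``/``amplitude_scale``
    emulate a subject's idiosyncratic timing and gain.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    fs = cfg.sample_rate
    montage = cfg.montage
    m = len(montage)
    duration_ms = float(onsets_ms[-1]) + 2 * cfg.pad_ms if len(onsets_ms) else cfg.pad_ms
    n_samples = int(round(duration_ms / 1000.0 * fs))
    signal = np.zeros((m, n_samples))
    t_axis = np.arange(n_samples) / fs * 1000.0  # ms

    # ERP components, trial by trial (bump evaluated on a local window only).
    for trial_idx, (label, onset) in enumerate(zip(sequence, onsets_ms)):
        onset = onset + cfg.pad_ms
        for tpl in templates:
            if not tpl.affects(label):
                continue
            jitter = rng.normal(0, tpl.trial_jitter_sd) if tpl.trial_jitter_sd else 0.0
            amp = (tpl.amplitude_uv + jitter) * (
                (1.0 - tpl.habituation_rate) ** trial_idx
            ) * amplitude_scale
            sigma = tpl.half_width_ms / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            peak = onset + tpl.peak_latency_ms + latency_shift_ms
            lo = max(int((peak - 4 * sigma) / 1000.0 * fs), 0)
            hi = min(int((peak + 4 * sigma) / 1000.0 * fs) + 1, n_samples)
            bump = amp * np.exp(
                -0.5 * ((t_axis[lo:hi] - peak) / sigma) ** 2
            )
            signal[:, lo:hi] += tpl.topography[:, None] * bump[None, :]

    # Background 1/f noise.
    if cfg.noise_rms_uv > 0:
        signal += _one_over_f_noise(
            rng, m, n_samples, fs, cfg.noise_exponent, cfg.noise_rms_uv
        )
    # Line interference (common phase, slight per-channel gain variation).
    if cfg.line_amplitude_uv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        gains = 1.0 + 0.1 * rng.standard_normal(m)
        line = np.sin(2 * np.pi * cfg.line_freq_hz * t_axis / 1000.0 + phase)
        signal += cfg.line_amplitude_uv * gains[:, None] * line[None, :]
    # Ocular blinks: Poisson events through a frontal topography.
    if cfg.blink_rate_hz > 0 and cfg.blink_amplitude_uv > 0:
        n_blinks = rng.poisson(cfg.blink_rate_hz * n_samples / fs)
        kernel = _blink_kernel(fs, cfg.blink_width_ms)
        topo = _gauss_topography(cfg.montage, "Fpz", spread_deg=35.0,
                                 include_eog=True)
        eogv = montage.index("EOGv") if "EOGv" in montage.labels else None
        if eogv is not None:
            topo[eogv] = 1.5  # EOG sits closest to the source
        starts = rng.integers(0, max(n_samples - len(kernel), 1), size=n_blinks)
        for s in starts:
            amp = cfg.blink_amplitude_uv * rng.uniform(0.7, 1.3)
            signal[:, s: s + len(kernel)] += amp * topo[:, None] * kernel[None, :]
    # Bad channels: DC offset plus extra noise/line.
    for bad in cfg.bad_channels:
        i = montage.index(bad.label)
        signal[i] += bad.offset_uv
        if bad.noise_rms_uv:
            signal[i] += rng.normal(0, bad.noise_rms_uv, size=n_samples)
        if bad.line_amplitude_uv:
            signal[i] += bad.line_amplitude_uv * np.sin(
                2 * np.pi * cfg.line_freq_hz * t_axis / 1000.0
            )

    events = [
        Event(int(round((onset + cfg.pad_ms) / 1000.0 * fs)), label)
        for label, onset in zip(sequence, onsets_ms)
    ]
    full_meta = {"paradigm_n_trials": len(sequence)}
    if meta:
        full_meta.update(meta)
    return Recording(
        sample_rate=fs, signal=signal, montage=montage, events=events,
        meta=full_meta,
    )


def ground_truth(templates, montage: Montage,
                 threshold: float = 0.5) -> dict:
    """Map of the class-specific effects embedded by the renderer.

    For each template affecting only one class, reports the channels whose
    topography weight reaches ``threshold`` of the peak and the time window
    ``peak ± half_width``.
    """
    effects = {}
    for tpl in templates:
        if set(tpl.classes_affected) == {STANDARD, DEVIANT_PREFIX}:
            continue  # common to both classes: carries no class information
        peak_w = np.max(np.abs(tpl.topography))
        if peak_w == 0:
            continue
        chans = [
            montage.labels[i]
            for i in range(len(montage))
            if abs(tpl.topography[i]) >= threshold * peak_w
            and montage.roles[i] == "eeg"
        ]
        effects[tpl.name] = {
            "classes": list(tpl.classes_affected),
            "channels": chans,
            "window_ms": [
                tpl.peak_latency_ms - tpl.half_width_ms,
                tpl.peak_latency_ms + tpl.half_width_ms,
            ],
            "amplitude_uv": tpl.amplitude_uv,
        }
    return effects


def simulate_recording(
    cfg: SimConfig,
    spec: ParadigmSpec | None = None,
    templates=None,
    subject: int = 0,
    session: int = 0,
    block: int = 0,
) -> Recording:
    """Convenience wrapper: sequence + render with per-subject variation.

    The per-subject latency shift and amplitude scale are drawn
    deterministically from ``cfg.seed`` and the subject index, so the same
    subject keeps their idiosyncrasies across blocks and sessions.
    """
    spec = spec or ParadigmSpec()
    templates = templates if templates is not None else default_templates(cfg.montage)
    subj_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(subject + 1)[-1]
    )
    shift = subj_rng.normal(0, cfg.subject_latency_shift_sd_ms)
    scale = float(
        np.exp(subj_rng.normal(0, np.log1p(cfg.subject_amplitude_scale_sd)))
    )
    block_key = (subject * 1000 + session * 10 + block) % (2**31)
    rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed, block_key)).generate_state(1)[0]
    )
    labels, onsets = generate_sequence(spec, rng)
    return render_recording(
        labels, onsets, templates, cfg, rng=rng,
        latency_shift_ms=shift if subject else 0.0,
        amplitude_scale=scale if subject else 1.0,
        meta={
            "subject": subject, "session": session, "block": block,
            "paradigm": spec.kind,
            "ground_truth": ground_truth(templates, cfg.montage),
        },
    )
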