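# Methods

This note documents the models, the numerical choices and the limits of
what the tests establish. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The decoding model

Single trials are m × n matrices (m channels, n samples) vectorized
channel-major (all time points of channel 0, then channel 1, …); the
layout is recorded in a model *fingerprint* so trained weights remain
portable and a tracker can reject incompatibly shaped epochs.

The decoder is linear logistic regression. Training minimizes

    J(w, b) = (1/N) Σ_i log(1 + exp(−y_i (wᵀx_i + b))) + λ‖w‖²,
    λ = c · v̄,

where y_i ∈ {−1, +1} (+1 = deviant), v̄ is the mean per-feature variance
of the training data, and the bias is unpenalized. Tying λ to v̄ makes c
unitless with respect to the μV scale of the features: scaling the data
by s rescales λ by s² and leaves the decisions unchanged (a property
test asserts this). The grid for c is [0.001, 0.01, 0.1, 0, 1, 10,
1000]; the value 0 denotes an unregularized fit (λ = 0), and
a log-spaced alternative (0 → 100) can be supplied through
`TrainConfig.c_grid`. Grid ties break toward larger c (the simpler
model).

Optimization uses L-BFGS-B with the analytic gradient; convergence is
declared at a projected-gradient norm below the tolerance (default
1e-5), and a finite-difference gradient check at the returned optimum is
part of the test suite. scikit-learn's `LogisticRegression` (with
C = 1/(2Nλ)) serves as an independent cross-check in a test, never as
the implementation.

Predictions: class "+" iff f(x) > 0; an exact tie predicts "−"
(deterministic, favouring the non-event class). The posterior is the
standard logistic p(+|x) = 1/(1 + e^{−f}), the unique sigmoid for which
p(f) + p(−f) = 1 and p ∈ (0, 1). Batch decision values
are computed with the same per-row reduction as the streaming path, so
online tracking reproduces batch values bit-exactly.

Cross-validation is stratified 10-fold with shuffled, seeded fold
assignment (the fold-construction rule is not dictated by the problem;
temporal-block folds can be emulated through the generalization
harness). The reported rate is the arithmetic mean of fold rates, and
out-of-fold decision values are retained for sorting and fusion.

## Chance-level statistics

The binomial confidence half-width is the Wald interval
z_{1−α/2}·√(p(1−p)/k). At k = 1000 and α = 0.05 this gives ±3.1%. The
Wald form does not reproduce the conventional small-k values (e.g. ±9.6%
at k = 100, which the Wilson score interval gives); both are exposed via
`binomial_ci(..., method=...)`, Wald being the default. No test pins the
k = 10 value, which matches neither interval.

The permutation test uses p = #(permuted ≥ observed)/n_perm with no
+1 smoothing; a zero count is reported as "< 1/n_perm". With a discrete,
heavily tied statistic (e.g. training accuracy on 40 trials) these
p-values are super-uniform and the test under-rejects; the calibration
test therefore uses a continuous statistic (AUC of a nearest-centroid
projection), for which the rejection rate at α = 0.05 lands in
[0.03, 0.07] over 200 seeded runs.

## The simulator

The generator is a *stated world*, not a tuning dial: its defaults are
the recording conditions of the emulated paradigms.

* Sequences: oddball blocks of 1000 trials with exactly 150 deviants
  (15%), deviants never adjacent and never first, so every deviant has
  an immediately preceding standard (exact-count allocation, uniform
  over admissible position sets via a combinatorial bijection);
  "optimal" blocks of 600 trials strictly alternating standards with
  five deviant subtypes, 60 each, shuffled. Onsets every 500 ms.
* Components: Gaussian-in-time bumps scaled by a fronto-central
  topography (Gaussian falloff in great-circle angle from FCz, 55°
  spread). Defaults: N1 (−2 μV, 100 ms, both classes), MMN (−3 μV,
  150 ms peak, 100 ms FWHM — spanning the classical 82–207 ms analysis
  window, deviant only), P3a (+3 μV, 300 ms, deviant only). Per-trial
  amplitude jitter (SD 0.5–1 μV) and a multiplicative habituation decay
  (1 − r)^t with r = 5e-4 emulate drift across a block.
* Noise: 1/f background synthesized in the frequency domain with random
  phases (exponent 1, RMS 10 μV — ongoing EEG dwarfs the 1–5 μV
  components, as in real mismatch recordings); 50 Hz line interference
  (2 μV, per-channel gain jitter); blinks as smooth positive transients
  (squared half-sine, 250 ms, ~120 μV) through a frontal topography with
  the vertical EOG channel closest to the source, at 0.1 Hz Poisson
  rate; optional bad channels with DC offsets and extra noise.
* Subjects: per-subject latency shift (SD 15 ms) and log-normal
  amplitude scale (≈15%) drawn deterministically from the seed, constant
  across that subject's blocks and sessions.

What a green test does **not** establish: real EEG has non-Gaussian,
non-stationary artifacts, correlated noise across trials, and
inter-subject topography differences far richer than a latency shift
and a gain. The simulator's montage is an idealized synthetic 10-10
layout generated from ring angles, not digitized positions. Absolute
classification rates on this world (≈60–67% at 300–600 balanced epochs)
happen to sit in the plausible range for the paradigm, but only the
qualitative structure — above-chance decoding, fronto-central
searchlight localization, graded quartile ERPs, fusion gains — should be
read as validated.

## Preprocessing

Stage order: per-epoch bad-channel repair → ICA → band-pass → baseline →
rejection → re-reference → crop → resample → baseline. Epochs are cut
wide (−200..600 ms) so the filter has padding around the final analysis
window (−50..450 ms).

* Epoch windows are half-open [start, end) on the sample grid (first
  sample at the first grid point ≥ start), which makes 500 ms at 256 Hz
  exactly 128 samples and 16 at 32 Hz. Out-of-bounds events are skipped
  with a warning, never zero-padded.
* Bad channels: flagged per epoch when |mean| > 35 mV or 50 Hz band
  power > 1000 μV². The power estimator is a Welch periodogram with a
  boxcar window of up to one second (≈1 Hz resolution), integrated over
  49–51 Hz; for an on-bin sinusoid of amplitude A it returns A²/2
  exactly, which the tests exploit as a closed form.
* Repair and the surface Laplacian use a Perrin-style spherical spline:
  g(x) = (4π)^{-1} Σ_{l=1}^{50} (2l+1)/(l(l+1))^4 · P_l(x), solved with
  a ridge of 1e-5 on the bordered system; the Laplacian kernel carries
  the extra l(l+1) factor. Repair requires ≥4 good scalp channels.
* ICA is scikit-learn FastICA (a spatially fixed linear
  independence-maximizing decomposition) fitted on at most 20 000
  concatenated samples (deterministic stride; a pure speed knob) and
  applied to all samples; with full-rank components the re-projection
  of all components reconstructs the input to < 1e-6 μV. The artifact
  rule scores each component by the mean across trials of the variance
  of its *back-projected* contribution and removes components above the
  grand mean of the scores. A variance rule over ICA components admits
  several formulations (e.g. thresholding per-trial), and raw source
  variances are degenerate under whitening (all unity) — back-projected
  contribution variance is the formulation that makes the rule
  discriminative; the threshold factor is configurable.
* Filtering: zero-phase (forward-backward) Butterworth band-pass, order
  4 per pass — ≥40 dB at 50 Hz for the 0.5–13 Hz default and ≤1 dB
  mid-band ripple, both asserted by tests. The 0.5 Hz corner rings for
  seconds, so `filtfilt` padding is scaled to ~3 time constants of the
  high-pass corner.
* Rejection: an epoch is dropped iff any *scalp* channel exceeds
  ±75 μV after baseline correction; EOG excursions alone never reject.
  ±100 μV is another threshold in common use for this recipe; 75 μV is
  the optimized default and the knob is exposed
  (`reject.threshold_uv`).
* Re-referencing: mastoid (subtract the mastoid-pair mean from scalp
  and mastoid channels), CAR (per-sample scalp mean), spline surface
  Laplacian, or none.
* Resampling: polyphase (anti-aliased) with the rational rate factor;
  128 → 16 samples for 256 → 32 Hz, reducing 8192 features to 1024
  (an 87.5% reduction).

The pipeline is label-agnostic; permuting epochs permutes outputs
identically for every stage except the ICA fit, whose strided subsample
makes it order-sensitive in practice (the permutation property is tested
with ICA disabled).

## Feature evaluation and tracking

AUC maps are computed per (channel, time) feature by midrank statistics
(exactly equal to exhaustive pair counting, asserted against an O(n²)
oracle); masking retains features with |AUC − 0.5| ≥ the mask value.
Searchlights run a full seeded CV per channel (spatial) or per time
point (temporal); ranking ties break by unit index; incremental
inclusion evaluates top-1, top-2, … and reports the argmax subset.
Component windows are inclusive on the nearest-sample grid: 82–207 ms
and 238–363 ms each retain 4 samples on the 32 Hz grid over −50..450 ms.

Fusion sums decision values over k non-overlapping same-class trials
(posterior = logistic of the sum; a mean-based variant is exposed since
the scaling of grouped outputs is not dictated). For Gaussian decisions
N(±μ, σ²) the fused accuracy is Φ(√k·μ/σ), the closed form the tests
check by Monte Carlo. The streaming tracker buffers k decision values
and emits on every k-th consumed epoch; grouping is by arrival order and
class-agnostic (labels are unknowable online). Offline, trials can be
sorted by decision value into contiguous groups (remainder spread over
the last groups, group-mean f non-decreasing by construction) or into
hit/miss/true-negative/false-positive outcome groups with deviant as the
target class.

Generalization harnesses train on concatenated partitions and test on
disjoint ones (block, session, subject or dataset keyed); partition
overlap is an error. Learning curves evaluate CV on the first N trials
in collection order.

## Design choices that were genuinely open

* EDF/BDF support is a minimal hand-rolled reader/writer pair (16-bit
  EDF, 24-bit BDF, physical scaling honored, events from a Status
  channel or a TSV sidecar) because no EDF library is part of the
  supported environment; it is not a general EDF+ implementation.
* The oddball generator never places a deviant at trial 0, so every
  deviant contributes a (preceding-standard, deviant) pair and a
  1000-trial block yields exactly 300 balanced epochs.
* Per-stage seeds in the experiment runner derive from the global seed
  via `SeedSequence(seed).spawn` in fixed stage order, so one integer
  reproduces every stochastic output byte-for-byte in the numeric
  reports.
* Acceptance-scale runs use full two-block sessions (2 × 1000 trials)
  for parameter recovery — the standard session design for the oddball
  paradigm — and a 400-trial block in the quick end-to-end script.

## Known limitations

* FastICA frequently stops at its iteration cap on EEG-like data; a
  warning is emitted and the partially converged unmixing is used. The
  component-selection rule, not the unmixing algorithm, is the
  load-bearing part.
* The Wald interval is anti-conservative at small k; use the Wilson
  option below ~100 observations.
* The surface Laplacian output is on an arbitrary CSD scale (no head
  radius is modelled); fine for decoding, not for physical
  interpretation.
* `learning_curve` requires ≥ 2 × folds trials per increment and errors
  otherwise rather than shrinking the fold count silently.
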