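# Methods

## Problem

Move-to-Earn (M2E) applications reward users for step counts measured by
their phone's inertial sensors. A cheap "auto-walker" — a mechanical cradle
that rocks the phone — registers steps without any walking. gaitguard
decides, for every two-second window of 6-channel IMU data (tri-axial
accelerometer in m/s², tri-axial gyroscope in rad/s, 100 Hz), whether the
motion is genuine human gait or machine-generated rocking. Two device
geometries are modelled: auto-walker 1 rotates the phone about its X-axis,
auto-walker 2 about its Z-axis.

## Pipeline

1. **Harmonization** (`signals_io`): recordings are resampled to 100 Hz by
   linear interpolation (harmonization only ever upsamples, so anti-aliasing
   is unnecessary), then cut into non-overlapping (200, 6) windows; trailing
   partial windows are dropped. The channel order `ax, ay, az, gx, gy, gz`
   is fixed everywhere. Sampling rates absent from file metadata are
   inferred as `round(1 / median(diff(timestamps)))`; the median is robust
   to isolated dropped-sample gaps. Train/test splits are drawn *within*
   each subject or device at ratio 0.8/0.2 (train = `floor(0.8 n)`), so no
   split pools across subjects; subjects or phones flagged unseen contribute
   every window to the generalization split.

2. **Features** (`features`): 29 per channel × 6 channels = 174 values.
   The 19 statistical features are: IAV (`Σ|x|`), MAV (`Σ|x|/n`),
   population variance and SD, RMS, mean, MAD (`median(|x − median x|)`),
   four moving-average summaries (mean of the signal — or of `|x|` —
   smoothed by a width-5 unweighted or width-5 triangular kernel),
   skewness `m₃/m₂^1.5`, excess kurtosis `m₄/m₂² − 3`, IQR
   (linear-interpolation quantiles), energy (`Σx²`), and four entropies:
   Shannon entropy of a 16-bin amplitude histogram, normalized spectral
   entropy of the DC-free power spectrum, sample entropy (m = 2,
   r = 0.2·SD), and normalized permutation entropy (order 3, delay 1).
   The 10 peak features are the indices and heights (x₁,y₁)…(x₃,y₃) of the
   three tallest strict local maxima re-ordered by index, plus the adjacent
   differences (x₂−x₁, y₂−y₁) and (x₃−x₂, y₃−y₂). Degenerate conventions:
   zero-variance signals have skewness, kurtosis and all entropies defined
   as 0; missing peak slots carry the sentinel (−1, 0) and differences
   involving a sentinel are 0; plateaus peak at their first sample; height
   ties break toward the earlier index. The moving-average widths, entropy
   estimators and bin counts are frozen interpretations — several standard
   definitions exist for each name, and these are the ones this package
   commits to (they are part of the model schema, so serialized models stay
   valid).

3. **Hybrid detector** (`models`): a compact 1-D convnet — two blocks of
   (conv width 5 → ReLU → max-pool 2) with 32 then 64 filters, a dense-64
   ReLU layer and a 3-way softmax — is trained with Adam (lr 2·10⁻³) on
   categorical cross-entropy for 10 epochs of 10 steps with batch 40, to
   separate gait (class 0) from the two auto-walker geometries (classes 1,
   2). Its probability vectors are then classified genuine-vs-fraud by a
   binary SVM head; the tuned operating point is a polynomial kernel with
   C = 1 and γ = 0.1, and a 5-fold cross-validated grid search over
   {linear, rbf, poly} × {0.1, 1, 10, 100} × {1, 0.1, 0.01, 0.001} (48
   configurations) is available. The convnet is implemented directly in
   numpy (im2col-style convolutions via `sliding_window_view`/`tensordot`),
   which keeps training to seconds on one CPU and makes every run bit-level
   reproducible under its seed.

   **Input scaling.** Windows are z-scored per window and per channel before
   entering the convnet. This makes the network invariant to amplitude,
   gain and constant offset — it reads waveform *shape*, which is exactly
   what transfers across phone models and subjects — and it is the main
   reason the hybrid detector generalizes where the feature baselines do
   not. Training-split channel statistics ("train") and raw inputs (None)
   remain available via `CnnHyper.standardize`.

   **Polynomial kernels use coef0 = 1** (the inhomogeneous form). On
   simplex-valued probability vectors the homogeneous cubic kernel takes
   values of order γ³ ≈ 10⁻³, and the fitted head degenerates to its
   intercept; with coef0 = 1 the decision values land at ≈ +1 for gait and
   ≈ −1 for auto-walkers with the class boundary at 0, which is the
   behavior the decision-value analysis expects.

4. **Baselines** (`models`): kNN (k = 3, uniform weights), random forest
   (200 trees, √-features, depth 7, Gini) and a polynomial SVM (C = 0.1,
   γ = 1) on the 174 features, each with its grid-search variant. The SVM
   standardizes features in-pipeline (polynomial kernels are
   scale-sensitive); kNN and RF consume raw features. Decision values are
   the signed boundary distance for SVM-family models and the genuine-class
   probability (neighbor fraction / tree-vote fraction) for kNN and RF.

5. **Evaluation** (`evalx`): a window is called genuine iff its decision
   value is strictly above the threshold. FNR (auto-walker accepted) and
   FPR (genuine rejected) are swept over 1,001 uniform thresholds per
   family range — [−2, 2] for the hybrid head, [−4, 4] for the plain SVM,
   [−0.25, 1.5] for the probability-scaled kNN/RF — and the EER is read at
   the FNR/FPR crossing with linear interpolation between bracketing grid
   points (closest grid point, with a warning, if the curves never cross).
   Reports round to 3 decimals, half away from zero.

## The synthetic benchmark

No external data ships with the package; `synthetic.make_benchmark`
generates the full study. The generators are phenomenological, not
biomechanical — their contract is to reproduce the contrasts that define
the problem:

* **Gait** is a sum of 4 harmonics of an instantaneous stride frequency
  (default 1.8 Hz) whose per-cycle period is lognormally jittered
  (CV 0.05–0.12 across subjects) with per-cycle amplitude jitter, a
  per-subject gravity-bearing bias, per-subject placement orientation
  (a 3 × 3 rotation of both sensor triads) and white sensor noise
  (0.25 m/s² / 0.05 rad/s).
* **Auto-walkers** rock at ≈ 2.78 Hz (ten thousand oscillations per hour)
  with per-cycle period CV 0.005 — more than an order of magnitude below
  the human range, the timing signature the classifiers exploit. The
  dominant angular rate sits on gyro-X (device 1) or gyro-Z (device 2);
  mounting imperfection leaks a fraction of it onto the other axes and
  tips gravity by a proportional wobble angle; the phone rides at a lever
  arm from the pivot, contributing centripetal (r·ω², at twice the rock
  frequency) and tangential (r·dω/dt) accelerations; device 1 additionally
  modulates gravity through sin θ/cos θ on ay/az. Each phone applies its
  own per-channel gain and offset.
* **Phone/cradle coupling**: every phone model records the same motion
  differently. Each phone draws a gain/offset profile plus a mechanical
  character — broadband vibration pickup ("rattle"), swing vigor (peak
  rad/s), off-axis leak, and pivot radius.

The benchmark (defaults: 32 seen + 12 unseen subjects, 2 seen + 4 unseen
phones, 72 s per recording ⇒ ≈ 3,170 windows) holds out generalization
sections the way field evaluations do: **unseen subjects** are drawn from a
much wider range than the seen ones — pace 1.2–2.6 Hz, quiet low-amplitude
and near-sinusoidal highly regular walkers (period CV down to 0.015, steep
harmonic decay), free placement orientation up to 90° — emulating
cross-corpus gait diversity; **unseen phones** span wider gains, offsets,
rattle, swing and leak than the two training phones; **over-time** sessions
re-record the seen phones with fresh seeds and a ±2% gain drift, standing
in for a repeated measurement weeks later.

This diversity is what makes the benchmark informative: hand-crafted
per-channel statistics are amplitude- and orientation-bound, so kNN, RF and
the SVM degrade on the unseen sections (EERs of order 0.1–0.5), while the
shape-reading convnet + SVM head stays at EER ≤ 0.05. What passing these
tests does **not** show: performance on real corpora, robustness to
non-walking activities, carrying-position changes within a recording, or
auto-walker geometries beyond the two modelled ones. The generator has no
real-device calibration; its oscillation amplitudes and noise levels are
plausibility choices, not measurements.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-group split streams are keyed by
  (seed, CRC32(group)) so one subject's assignment never depends on which
  other subjects exist. Simulators are pure functions of (params, seed).
* Resampling preserves duration to within one sample period and is the
  identity when rates already match.
* The stride parameter of the windower exists but defaults to
  non-overlapping windows, avoiding train/test leakage through shared
  samples.
* Sample entropy is the O(n²) Chebyshev-template count, vectorized;
  `-log(A/B)` is defined as 0 when either count is 0.
* `rms² = variance + mean²` holds exactly under the population-normalized
  definitions and is asserted in the test suite as a cross-implementation
  identity.
* EER is invariant under strictly increasing transforms of the scores up to
  grid resolution; the suite checks this property explicitly.
* Serialized model bundles carry the feature schema and standardization
  mode; predictions reject inputs whose schema differs.

## Known limitations

* The convnet's training protocol (400 samples per epoch) is deliberately
  small; on much larger benchmarks the fixed step budget, not the data,
  bounds accuracy.
* The binary SVM head is uncalibrated — decision values are margins, not
  probabilities.
* The generator's gravity handling is a constant bias plus first-order tilt
  terms, not orientation dynamics; windows never span posture transitions.
* Single-channel dropout, temperature drift and timestamp jitter in real
  phone recordings are not modelled.
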