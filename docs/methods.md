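# Methods

## Signal model and pipeline

The package analyzes cyclic, submaximal trunk-extension exercise: ~25
cycles of ~4 s, each an eccentric half (upright 0° → 40° flexion,
resisting the load) followed by a concentric half (40° → 0°, moving it).
Surface EMG is recorded at 2 kHz from six back-extensor sites (L5
multifidus, L2 longissimus, L1 iliocostalis lumborum, both sides); a
single-axis accelerometer (160 Hz) on the dynamometer lever arm tracks
the movement.  Two per-cycle scalars are extracted per channel and phase
— MVC-normalized RMS amplitude and instantaneous median frequency (IMDF)
— and summarized by a least-squares line whose intercept ("initial
value") and slope (as % of the intercept per second) are the fatigue
indices.

## Kinematics and segmentation

* Trunk angle is the arcsine of the gravity projection, `α = asin(acc/g)`
  — an approximation that ignores the lever arm's tangential
  acceleration, adequate for segmentation.  Ratios marginally above 1
  (|acc/g| ≤ 1.05) are clamped with a warning; beyond that the sensor is
  deemed miscalibrated and an error is raised.
* Angular velocity: 8th-order Butterworth 1 Hz low-pass applied
  forward-backward (zero phase), then a central first difference.
* Cycle detection operates on the 1 Hz-filtered angle: alternating
  minima/maxima with a minimum separation of 0.4 × the nominal cycle
  duration and 10% prominence; runs of same-type extrema collapse to the
  most extreme one.  Virtual extrema are padded at the trace ends so edge
  half-cycles are bookkept (and flagged) rather than dropped silently.
* Within each half-cycle only a centered window (default 1.0 s of the
  ~2 s half-cycle) is retained, so movement velocity and muscle-length
  range are comparable across phases and cycles.  A half-cycle is flagged
  when |angular acceleration| inside its window exceeds the trial's 90th
  percentile — a scale-free operationalization of "disproportionally
  large" trunk acceleration.  The first and last `omit_edge` (default 2)
  cycles are flagged as edge cycles.  Fewer than `min_cycles` (default
  15) fully retained cycles aborts the trial.
* Spans are converted to the SEMG clock as half-open, 0-based sample
  intervals.

## Pre-filtering and amplitude normalization

SEMG is band-passed 20–500 Hz (4th-order Butterworth high- and low-pass,
forward-backward; order is a package choice, the cutoffs are the
protocol's).  Amplitude is normalized per channel by the RMS of a
sustained 80% MVC isometric reference over its [2 s, 5 s) window —
half-open by convention, giving exactly 3 s.

## Time-frequency distribution and IMDF

Cyclic contractions make the SEMG non-stationary, so spectra are
estimated with a Cohen-class bilinear distribution rather than
windowed Fourier methods.  The kernel is the Choi-Williams exponential
`exp(-θ²τ²/σ)` (σ = 1 by default; smaller σ smooths harder) multiplied
by a short fixed time window (Hamming, ~60 ms).  The fixed factor
matters for broadband signals: the Choi-Williams kernel's time-smoothing
width is proportional to the lag, so small-lag components of noise-like
signals are essentially unsmoothed; after negativity clipping their
fluctuations bias median-frequency estimates upward by several Hz.  With
the product kernel the bias on calibrated synthetic EMG is within ~1 Hz.
Implementation details:

* analytic (Hilbert) signal; instantaneous autocorrelation smoothed in
  time per lag; Hamming lag taper (suppresses ringing from the finite
  lag support, ~256 samples); FFT length = next power of two ≥ 2× the
  segment length, capped at 16384 (beyond ~4 s segments the grid is
  already much finer than any EMG spectral feature).
* the surface is scaled so a column sum approximates instantaneous
  power; negative values — unavoidable in bilinear distributions — are
  clipped to zero and their energy fraction recorded.
* IMDF per instant: the frequency where cumulative power crosses half
  the total, with each bin's power spread uniformly over the bin (so a
  single-bin spectrum returns exactly that bin's center).  The segment
  summary is the median over the (default 128) instants, robust to edge
  artifacts; a segment with > 50% undefined instants is missing.

## Trend fitting and aggregation

Per-cycle values are regressed on segment mid-time in seconds from
exercise onset (time, not cycle index, because slopes are reported in
%/s).  The initial value is the intercept at t = 0 — extrapolated, not
the first retained point, so excluding early cycles does not shift the
time origin.  Normalized RMS series are fit after MVC normalization;
IMDF series are fit in Hz and only the slope is normalized, matching the
convention of reporting IMDF initial values in Hz.  Aggregation averages
left/right trend parameters within level, takes the three-level mean as
the "all electrodes" entry, and selects the "most negative electrode"
(smallest normalized slope among the six channels) independently per
parameter and phase.

## Robust statistics

Fatigue indices across subjects are skewed, so group contrasts use
percentile-bootstrap median tests (default 2000 resamples, seeded):

* one-way, paired by default (each subject contributes both phases):
  bootstrap over subjects of the median within-subject difference;
  two-sided equal-tailed p with half-weight on zeros.
* two-way 2×2 (age group × gender) on conc/ecc ratios: cell medians are
  bootstrapped within cells; main effects are differences of
  factor-level mean cell medians, the interaction is the difference of
  differences.  Age is binned at the cohort median by default.

Monte-Carlo calibration (paired, n = 40, lognormal, 1000 null datasets)
puts the empirical type-I error at ≈ 0.05.  A caveat documented here
deliberately: at very small n (≤ 12) with borderline effects, percentile
bootstrap and exact sign-flip permutation p-values are different
functionals of the data and can disagree by far more than Monte-Carlo
error; they agree where the comparison is informative (clear separation,
or identical groups).  No multiple-comparison correction is applied.

## Synthetic-data generator

The generator emulates the study conditions — 25 cycles × 4 s, 0–40°,
six channels at 2 kHz, accelerometer at 160 Hz, ≤ 0.75 µV RMS noise
floor — with known ground truth for recovery testing:

* **Kinematics**: each half-cycle follows a paced profile — half-cosine
  velocity blends over the first and last 20% and constant velocity in
  between (peak ≈ 25°/s for the defaults), like a metronome-paced
  movement.  Acceleration is confined to the turnarounds, which is what
  makes a trial-relative acceleration threshold meaningful; real
  subjects' mid-range velocity fluctuations are not modeled.  The
  accelerometer trace is the exact gravity projection `sin(α)`.
* **EMG**: per half-cycle, Gaussian noise shaped to the classic two-pole
  surface-EMG spectrum `S(f) ∝ fh⁴f² / ((f²+fl²)(f²+fh²)²)` with
  fh = 2.5·fl, band-limited to the 20–500 Hz recording band (like
  hardware-filtered EMG).  The pole scale is solved by bisection so the
  band-limited spectral median equals the drifted IMDF target; the
  amplitude is scaled so the post-pre-filter RMS equals the drifted RMS
  target (the predicted shrinkage of the zero-phase 20/500 Hz cascade on
  the shape is divided out).  Drift is piecewise-stationary: parameters
  are frozen within a half-cycle and evaluated at its mid-time, matching
  the per-cycle resolution of all downstream estimates.
* **Defaults are the study conditions**: initial concentric RMS 121 µV
  against an MVC reference of 100 µV (normalized 1.21),
  concentric/eccentric amplitude ratio 1.85, RMS drift +0.13 %/s
  (concentric) and 0 (eccentric), IMDF drift −0.11 %/s (both phases),
  initial IMDF 70/57/53 Hz for L5/L2/L1 — the medians reported for
  healthy adults in this exercise.
* Ground truth (phase spans, per-half-cycle targets, MVC RMS) is
  emitted as a sidecar that the analysis pipeline never reads.

What passing recovery tests do and do not show: the generator's
half-cycles are independent shaped-noise realizations with exact
amplitude calibration — real EMG has amplitude modulation within
half-cycles, inter-cycle correlation, motor-unit structure and
nonstationarity within segments, none of which are modeled.  Recovery
therefore validates the estimator chain (segmentation → TFD → IMDF/RMS →
regression → aggregation), not the physiological fidelity of any real
recording.

## Problem sizes

Parameter recovery uses 20 trials of 25 cycles × 6 channels (the full
study geometry); bootstrap calibration uses 1000 null datasets of n = 40
with 2000 resamples each; end-to-end pipeline tests use 20-cycle trials
with coarser IMDF grids.  These sizes were chosen to make the whole
suite comfortably reproducible on a single core.

## Known limitations

* The Choi-Williams IMDF of broadband EMG retains a small positive bias
  (≈ 1 Hz on 4 s segments and ≈ 3–4 Hz on 1 s segments at ~60 Hz
  medians); it largely cancels in normalized slopes but inflates
  absolute initial IMDF values slightly.
* The arcsine angle model ignores tangential acceleration of the lever
  arm; no multi-axis fusion is attempted.
* The exact kernel family/σ and the regression abscissa used in prior
  hardware-based analyses of this exercise are not standardized; both
  are exposed as configuration.
* `median_test_twoway` requires a complete 2×2 design with ≥ 5
  observations per cell.
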