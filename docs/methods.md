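# Methods

## Sessions and preprocessing

A session is one variable-length tri-axial accelerometer recording
(g-units, seconds) of the rapid alternating pronation–supination task,
labeled in its entirety as dyskinetic (1) or not (0). Full task windows are
retained — no truncation, padding or resampling anywhere — because the
clinical label applies to the whole task and shorter fixed windows would
discard task structure. Sessions shorter than 5 s (configurable) are
excluded with a logged reason. Timestamps may be mildly irregular; the
sample rate is the average rate `(n−1)/(t_last−t_first)` and only spectral
features rely on it. Inputs declaring m/s² are divided by 9.80665.

Device coordinate frames differ across wearables and wearings, so each
session receives a **global rotation** mapping its mean acceleration onto
+z. The gravity estimate is the plain session mean (no low-pass filter):
the task is quasi-stationary at the torso, and a filter would add a cutoff
parameter with no principled value. The rotation is the minimal (geodesic)
one in the plane spanned by the mean vector and +z; the yaw about gravity
is left undetermined because the downstream per-session PCA is invariant
to it. A mean-vector norm below 0.1 g means there is no stable gravity
estimate and is an error.

## Semantic representation

**Projection.** PCA is fit per session on the 3×3 covariance of the
centered data; the PC1 scores form a one-dimensional movement trace.
Per-session (rather than cohort-global) fitting makes the representation
invariant to device orientation and cannot leak information across
train/test splits. The component sign is fixed from the trace itself: it is
flipped so the first sample whose |score| reaches half the trace's peak is
positive. Because |scores| are invariant under rigid rotations of the raw
vectors, this convention is rotation-stable; a loading-based convention
(largest-magnitude loading entry positive) is not, and an argmax-|score|
rule hits an exact ± tie on symmetric oscillations.

**Parts and segments.** The trace is split into contiguous
beginning/middle/end parts of sizes `n − 2⌊n/3⌋, ⌊n/3⌋, ⌊n/3⌋` (remainder
deterministically to the beginning). Each part is cut at zero crossings
into maximal constant-sign runs; zero-valued samples attach to the
preceding run. Runs shorter than 2 samples are merged into the preceding
segment, and the same-sign run that follows an absorbed glitch coalesces
with it, so one noisy sample never splits a half-cycle; every sample stays
in some segment, hence segment durations tile the part exactly. Each
segment carries its extremum (the maximum-|value| sample) whose sign names
it a pronation or supination half-cycle. Zero-crossing segmentation is used
rather than fixed-equal-length segmentation: for a near-periodic task the
two coincide, and only the former makes segment counts and durations
informative when the movement degrades.

**Features (25).** With `S_p` the segments of part `p`, maxima/minima the
extrema of positive/negative segments:

| kind | definition |
|---|---|
| `abs_mean_extremum` | mean of \|extremum\| over all segments, whole measurement |
| `n_segments(p)` | segment count |
| `duration_ratio(p)` | total positive / total negative segment duration (pronation–supination asymmetry) |
| `mean_duration(p)`, `iqr_duration(p)` | mean and IQR of segment durations |
| `relmax_mean(p)`, `relmax_iqr(p)` | mean and IQR of maxima |
| `relmin_mean(p)`, `relmin_iqr(p)` | mean and IQR of minima |

IQRs use linear-interpolation quartiles. `abs_mean_extremum` averages
magnitudes (not the magnitude of the average) so symmetric oscillations do
not cancel. Degenerate statistics — a part with no segment of the needed
sign, or fewer than two values for an IQR — take finite sentinels
(1 for the duration ratio, 0 otherwise) and are flagged, because the
classifiers downstream reject NaN and silent dropping would misalign the
matrix. Amplitude-scaled features scale linearly with the signal; counts,
durations and the duration ratio are scale-free; all 25 are invariant
under rigid rotations of the raw data (verified to 1e−6 relative in the
tests, observed at ~1e−15).

## Automatic features and relevance filtering

The automatic catalogue computes 62 named features per series —
distributional statistics and quantiles, counts/run-lengths/locations,
successive-change statistics, autocorrelation at lags 1–10, linear trend,
energy, band powers over 0.5–3 / 3–7 / 7–12 Hz (absolute and relative),
spectral entropy, dominant frequency, spectral centroid, and a
sample-entropy approximation (strided to ≤256 points to bound the O(n²)
cost). Series are linearly detrended before the FFT; spectral features use
the session's average rate. Constant or too-short series fall back to
documented zero floors so the matrix stays finite. `PCA_AUTO` featurizes
the PC1 trace; `AUTO3D` featurizes each raw axis with axis-prefixed
columns (exactly 3× the width). The catalogue is deterministic with stable
column names; a comprehensive third-party extractor could be substituted
behind the same interface, at the cost of library-dependent columns.

Relevance filtering tests each feature against the binary label
(Mann–Whitney U for real features, Fisher's exact for binary ones) and
retains Benjamini–Hochberg rejections at FDR 0.05 (default); constant
columns are removed first. The filter is fit **inside each CV fold on the
training split only** — pooled filtering would leak test labels into
feature selection. Since the retained set depends on the fold, not the
model configuration, it is cached per fold.

## Model selection

The grid is classifier × hyperparameters × selector × sampler. Defaults:
logistic regression C ∈ {0.1, 1, 10}; k-NN k ∈ {5, 11}; random forest 100
trees, depth ∈ {5, unlimited}; RBF SVM C ∈ {0.1, 1, 10}; gradient-boosted
trees 100 estimators, learning rate ∈ {0.1, 1.0}; selector ∈ {none, 5, 10}
(ANOVA F, ties broken by column name); sampler ∈ {none, SMOTE} — 72
configurations. Each is scored by stratified 10-fold CV (folds shared
across configurations for a given seed; k reduced with a warning if the
minority class is smaller than k). The per-fold pipeline order is
impute (train medians) → relevance filter → SMOTE → selector →
standardize → fit, every step fit on the training fold only;
standardization applies only to scale-sensitive classifiers (logistic
regression, k-NN, SVM). SMOTE synthesizes each new minority row as
`m + u·(nbr − m)` with `nbr` one of the k = 5 nearest minority neighbors
and `u ~ U[0,1]`, preserving originals and equalizing class counts.
Leaderboards rank by **mean** fold macro F1 (pooled confusion matrices are
still emitted), ties by higher mean accuracy then lexicographic
configuration id; a configuration failing on any fold scores 0 with a
logged error rather than disappearing. A master seed fans out to folds,
SMOTE and stochastic classifiers, making leaderboards bit-reproducible.

## Transfer evaluation

The top-10 source configurations are refit on the **full** source set
(same pipeline, fit on source only) and predict the target cohort once.
Refitting on all source data — rather than reusing fold-fitted estimators
— is the standard deployment protocol and uses every labeled source
session. Representations are compared by Welch's unequal-variance t-test
over their 10 transfer scores, flagged significant at p < 0.001. The mean
CV-to-transfer macro-F1 drop per representation quantifies overfitting to
the source site.

## Synthetic cohorts

No public signal model exists for this task, so the generator derives one
from the physics: pronation–supination mainly re-orients gravity in the
wrist sensor frame. The wrist angle is `θ(t) = A·sin(2πft + φ)` about the
forearm (x) axis; the sensor reads the rotated gravity vector plus a
tangential term `r·θ''/g₀` (lever arm r = 3 cm) and white noise. `A` is an
angular amplitude in radians (0.4–0.9 by default); the g-scale signal
follows from the geometry. Dyskinetic sessions add to θ a unit-RMS
band-limited (1–4 Hz) stochastic oscillation scaled to
`dysk_severity·A/√2`, amplitude-modulated at 0.1–0.3 Hz (depth 0.5), plus
Poisson jerk transients (0.2/s, 50 ms decay) — a caricature of choreiform
LID, not a biomechanical claim. At severity 0 the overlay is exactly zero
and the classes coincide; at severity 1 its RMS matches the voluntary
movement's. Defaults: 25 subjects × 2–6 sessions, prevalence 0.3, 50 Hz,
10–30 s, pacing 0.8–2.0 Hz with ±10 % session drift; subjects share
amplitude, pace and a tilted wearing orientation (tilt sd 0.25 rad) across
their sessions. The `shifted_site` preset doubles the noise, drops the
rate to 30 Hz and tilts gravity 60°, emulating a second clinic with a
different device.

What the simulator does **not** emulate: real LID phenomenology and
severity grading, tremor or bradykinesia, free-living activity,
device-specific noise spectra, or label noise from imperfect clinical
scoring. Passing tests therefore demonstrate that the pipeline recovers a
known planted effect and that the representations differ in shift
robustness for the stated physical reasons — not clinical performance on
real cohorts, whose headline scores require restricted data.

## Problem sizes and numerical choices

The end-to-end experiments use a ~240-session source cohort (60 subjects)
with a ~190-session identically distributed target for the main grid
search and transfer, and eight generator seeds of ~50/40-session
source/target pairs with a reduced 10-configuration grid for the
site-shift robustness experiment; these sizes give stable estimates in a
few CPU-minutes. Tolerances: rotation isometry asserted at 1e−9 relative;
PC trace mean at 1e−9; orientation invariance at 1e−6 relative; metric
oracles at 1e−12. Degenerate inputs (constant signals, single-class
labels, singleton minorities, too-short series) raise descriptive errors
or take documented sentinels as listed above.

## Known limitations

Severity is a single dial, not a clinical scale; per-subject label
correlation is simulated only through shared movement parameters, and the
evaluation splits sessions, not subjects. The automatic catalogue is a
documented 62-feature core, far smaller than exhaustive extractors — large
enough to expose the representations' contrast, but not a drop-in
replacement for them. Confusion-matrix plots are optional and require
matplotlib.
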