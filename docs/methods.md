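# Methods

## Overview

`rigidnet` implements a two-armed analysis of motor rigidity in a
pursuit-tracking paradigm: (i) system identification of tracking behavior,
summarized by the damping ratio of a fitted second-order model, and (ii)
directed network inference over ROI time series with FDR control, followed
by sparse prediction of clinical rigidity scores from per-subject
connection strengths. A synthetic-data module defines the study conditions
and supplies every input with ground truth.

## Tracking arm

### Generative model

The target is `u(t) = m + a·sin(2π f t)` with midpoint `m = 10 %MVC`,
half-range `a = 5 %MVC` and `f = 0.5 Hz`, sampled at 50 Hz for 90 s — the
task's nominal force corridor of 5–15 %MVC. The response is the zero-order
hold (ZOH) discretization of the unity-DC-gain second-order system

    G(s) = ω_n² / (s² + 2ζω_n s + ω_n²),

driven by the sampled target from rest, plus i.i.d. Gaussian measurement
noise (default study condition: sd 0.1 %MVC, i.e. 1% of the target range).
ZOH is used because the subject sees a discretely rendered target, and it
makes the discrete model exactly representable by the identification
stage, giving an algebraically exact round trip on noise-free data.
Maximum voluntary contraction is calibrated as the median of a 15 s
maximal-squeeze pressure trace (median, not mean, so a transient spike
does not inflate the calibration).

### Identification

`fit_lds` estimates the discrete model `x_t = A x_{t-1} + B u_{t-1}`,
`y_t = C x_t + D u_t` (order fixed at 2). Two methods are provided:

* **`arx`** — least-squares regression of `y_t` on
  `[y_{t-1}, y_{t-2}, u_t, u_{t-1}, u_{t-2}]`, converted to state space.
  Exact on noise-free second-order data (poles recovered to ~1e-10), but
  inconsistent under output noise: the lagged-output regressors are
  correlated with the noise, and with a narrowband (single-sinusoid) input
  the bias is severe at 50 Hz sampling — in practice the second pole
  collapses toward −0.5 and the fit loses its second-order interpretation.
* **`oe`** (default) — output-error refinement: starting from the ARX
  solution (or a coarse grid when the ARX poles are uninterpretable),
  minimize the *simulation* error over the (ζ, ω_n, gain) family of
  ZOH-discretized second-order systems with a Levenberg–Marquardt search
  on (log ζ, log ω_n, gain). Consistent under white output noise; under
  the study's noise conditions the median |ζ̂ − ζ| is ~1e-3 across
  ζ ∈ {0.3, 0.7, 1.2}, ω_n ∈ {2, 5} rad/s. Although the steady-state
  response to a single sinusoid carries only two constraints (gain and
  phase at the target frequency), the fixed unity-structure family has
  only two shape parameters, so the fit is well posed even ignoring the
  onset transient.

### Metrics

Fitted discrete eigenvalues map to continuous poles by the principal
logarithm, `s = log(λ)/dt`. Eigenvalues on the non-positive real axis are
flagged *degenerate* (no real-valued second-order system at this sampling
rate produces them) rather than force-fitted. From a pole pair:

* conjugate pair: `ω_n = |s|`, `ζ = −Re(s)/|s|`;
* real pair: `ω_n = sqrt(s₁ s₂)`, `ζ = −(s₁+s₂)/(2ω_n)`;
* peak time `π/(ω_n sqrt(1−ζ²))` for ζ < 1, undefined otherwise;
* settling time: the 2% band approximation `4/(ζω_n)` (no band is
  canonical; 2% is the common control-texts default) alongside the exact
  last 2%-band crossing of a simulated unit-step response;
* rise time: 10%→90% measured on the simulated step response
  (exactness preferred over the usual approximation formulas).

Per-subject aggregation defaults to the mean of ζ and ω_n over
non-degenerate runs (median selectable); the timing metrics are recomputed
from the aggregated parameters so the summary is internally consistent.
RMS errors across visual-noise levels are compared by one-way ANOVA.

## Connectivity arm

### Generative model

ROI series follow a stationary lag-1 vector autoregression
`x_t = W x_{t-1} + e_t` with Gaussian innovations, spectral radius of `W`
below 1 enforced, and a 200-sample burn-in discarded. Cohorts attach to
each subject a perturbed copy of the base `W` — multiplicative Gaussian
jitter (default sd 20%) on nonzero coefficients plus a small additive
strength noise (default sd 0.05) on every edge slot. The additive term
represents estimation-level variability of connection strengths and keeps
the cohort design matrix full rank; without it, columns for
zero-coefficient edges would be identically zero. Scores follow
`Y = Xβ + ε` with sparse β; an optional ordinal mode clips and rounds `Y`
to the clinical [0, 20] range (off by default — the published regression
treats the score as continuous). The between-subject variance structure of
connectivity is not identified by anything in the data we emulate; the
jitter model is an explicit stand-in.

### Preprocessing

Voxel-level inputs (optional) are linearly detrended per voxel and averaged
within ROI. Drift removal projects out a discrete-cosine basis with
`K = floor(2·T·TR/cutoff) + 1` regressors (cutoff 128 s), the convention of
standard fMRI drift-removal implementations; the operation is a linear
projection, hence idempotent and additive. Columns are then standardized.
Whether standardization preceded the published analysis is not knowable
from the record; it is configurable and on by default.

### Structure learning

The learner operates on pooled lagged sample pairs: each run contributes
`(x(t-1), x(t))` rows, standardized per run, never crossing run or subject
boundaries. Direction comes from temporal precedence only (lag-1 → present),
so the edge universe is the `R(R−1)` ordered pairs without self-loops —
2,652 for 52 ROIs.

The algorithm is PC-style with an embedded FDR screen. For conditioning-set
sizes L = 0 … `max_cond_size` (default 3, a sample-size compromise at
~270 timepoints per run):

1. for each surviving edge (i → j), test the partial correlation of
   `x_i(t-1)` and `x_j(t)` given every size-L subset of j's other surviving
   candidate parents, with the Fisher-z test
   (`z = atanh(r)·sqrt(n − |S| − 3)`); keep the edge's running maximum
   p-value; a singular conditioning covariance yields p = 1 (conservative);
2. after each sweep, apply Benjamini–Hochberg at level q (default 0.05) to
   the running maxima over surviving edges and drop edges no longer
   rejected as independent.

Edges are processed in lexicographic (source, target) order so ties and
output order are deterministic. The contract asserted by the test suite is
FDR control of the reported edge set: over 100 replicates of sparse
ten-region networks (10% density, coefficient 0.4, 20 subjects × 250
timepoints) the empirical FDR is ~0.057 against the 0.05 + 2 Monte-Carlo-SE
bound, with power ~1.0. Exact support recovery is a different property: at
level q the procedure *admits* ~q false discoveries by design, so
support consistency is only expected (and is tested) at a stringent level
(q = 0.01) with generous conditioning and large samples. At high in-degree
(e.g. 227 true edges among 52 ROIs, mean in-degree ~4.4 > `max_cond_size`),
some false edges survive because no tested conditioning set contains all
true parents; raising `max_cond_size` trades power and runtime for
specificity.

An effective-sample-size (Bartlett) correction for autocorrelated series is
available but off by default; the calibration suite runs on
white-innovation VARs where the uncorrected test is exact.

### Strengths

Given the group network, per-subject strengths are the per-target OLS
coefficients of `x_j(t)` on the subject's `{x_i(t-1): i ∈ parents(j)}` with
intercept — the linear-Gaussian dynamic-Bayesian-network estimate. This
reduces exactly to normal equations per target (verified against a
brute-force oracle to 1e-10); a discrete-CPD variant is out of scope, the
linear-Gaussian form being the natural choice for continuous series.

## Prediction arm

The global rigidity score is the sum of five ordinal 0–4 items. The design
`X` (subjects × edges) and scores `Y` enter a LASSO with internally
standardized columns:

    min_b (1/2n)||y − Xb||² + λ||b||₁

solved exactly along the LARS path and interpolated onto a 100-point
log-spaced grid from λ_max = max|Xᵀ(y−ȳ)|/n down to a `lambda_min_ratio`
of 1e-4 (1e-2 when p ≥ n, the glmnet convention). λ is chosen to minimize
the mean squared 10-fold cross-validation error — the "least predictive
error" rule — with the one-standard-error rule behind a flag. Fold
assignment is a seeded balanced partition; when folds equal subjects it
degenerates deterministically to leave-one-out, which is exactly the
published setting of 10 folds on 10 subjects. Reported coefficients are
de-standardized to the original column scale, so scaling a column by c
divides its coefficient by c without changing the selection.

Two properties of minimum-CV-error LASSO selection at the small-cohort
scale are worth stating plainly, because the test suite asserts them:

* With n = 50 subjects and p = 227 edges (9 strong true effects), the
  *true* edges are essentially always selected (≥ 80% of replicates
  recover all nine), but the chosen support strictly over-selects —
  typically ~40 columns — and the true support is almost never an exact
  segment of the LASSO path at this aspect ratio, so no λ rule can return
  it exactly. Exact-support selection is achievable only in easier regimes
  (e.g. orthonormal designs with the parsimonious 1-SE rule).
* At n = 10 the selection is unstable across data draws; the instability
  is asserted by a test, not hidden.

Selected edges are refit by robust regression: iteratively reweighted
least squares with Tukey bisquare weights (tuning constant 4.685, ~95%
Gaussian efficiency), scale estimated by the normalized median absolute
deviation, intercept included; p-values use t statistics on n − k − 1
degrees of freedom. These are the documented defaults of the standard
robust-fitting routine the procedure mirrors. If an exact fit leaves zero
residuals the coefficients are returned with zero standard errors and NaN
p-values rather than dividing by a zero scale. Post-selection p-values are
naive refit values, faithful to the mirrored procedure; they are not
adjusted for selection. Group differences in per-edge strengths use
Welch's t test (Student's behind a flag).

## Pipeline

The orchestration layer fans one global seed into per-stage seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`, writes only plain-text
artifacts (CSV/TSV/JSON with repr-precision floats), and records a manifest
with the config hash and a SHA-256 per output; reruns with the same config
are byte-identical and are skipped unless forced. Visual path-noise levels
(0/25/50%) are carried as trial labels only — the analysis pools runs, so
the noise level is not modelled dynamically. The simulated cohort couples
the two arms: each subject's generating ζ increases linearly with their
rigidity score (gain 0.15 per score-SD, jitter sd 0.05, clipped to
[0.15, 2.5]), emulating the reduced overshoot of rigid subjects, so the
end-to-end run exhibits a recoverable ζ–rigidity association.

Default problem sizes — 10 patients + 10 controls, 52 ROIs, 227 true
connections (8.6% of the 2,652-edge universe), 270 timepoints per subject,
three 90 s tracking runs per subject — mirror the study design the
generator emulates; the Monte-Carlo studies in the acceptance script use
100 replicates/seeds per condition, which bounds Monte-Carlo standard
errors near 0.02 for proportions.

## What the synthetic data does not capture

Linear Gaussian VAR series lack hemodynamic convolution, physiological
noise spectra, head-motion artifacts and inter-regional lag structure
beyond one TR; tracking noise is white, whereas real motor noise is
signal-dependent; rigidity scores are generated continuous, not ordinal,
by default. Passing recovery tests therefore demonstrates correctness of
the estimators under their stated assumptions, not robustness to the full
physiology of real recordings. ROI extraction, motion and slice-time
correction, and spatial normalization are upstream of this package and out
of scope.
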