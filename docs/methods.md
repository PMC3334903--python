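# Methods

`pmkinetics` analyzes Phenotype MicroArray (PM) respiration kinetics: for
each well of a 96-well plate the instrument records color intensity in
OmniLog units (capped at 400) every 15 minutes, typically over 91 hours,
giving one respiration curve per well. The package reduces each curve to
four shape parameters — lag phase λ (h), maximum slope μ (units/h),
maximum height A (units) and area under the curve (AUC) — by three
methods, attaches bootstrap confidence intervals, detects differences
between curves and groups of curves, and classifies curve shapes by
archetypal analysis. A synthetic-data generator reproduces the factorial
designs and the curve-shape taxonomy of real production runs so that
every component is testable without instrument data.

## Estimation methods

### Native instrument algorithm (`pmkinetics.native`)

A re-implementation of the parametric algorithm of the instrument
software, which works on a handful of order statistics and threshold
crossings of the raw readings (no model, no interpolation):

* MaxHeight = the reading at the 10th-percentile-from-the-top rank over
  all time points. We read this as the nearest-rank 90th percentile;
  the alternative literal reading, "the 10th-highest reading", is a
  config switch (`max_height_rule="tenth_highest"`) because the source
  phrasing is ambiguous.
* MinHeight = the 12th smallest value among the first 48 readings
  (rank capped and flagged `short_series` for shorter series).
* MidHeight = (MinHeight + MaxHeight)/2; MidTime = the first time a
  reading strictly exceeds MidHeight; *x*% Time = the first time a
  reading exceeds MinHeight + x%·(MaxHeight − MinHeight).
* Slope = the total rise over the readings from 15% Time to one sample
  before MidTime plus the total rise from one sample after MidTime to
  85% Time, divided by (85% Time − 15% Time). "One sample" because the
  algorithm operates on discrete reads; the per-segment-slope-sum
  reading is rejected since its units would not be a slope after the
  division.
* λ = MidTime − (MidHeight − MinHeight)/Slope; A = MaxHeight;
  AUC = the plain sum of all readings (a step-function convention whose
  units are unit·reads, and which overestimates a trapezoidal integral
  for steep curves).

Flat curves never cross MidHeight: λ and μ are then undefined (NaN,
flagged), while A and AUC are still reported. The method provides no
confidence intervals.

### Growth-model fitting (`pmkinetics.growth_models`)

Four classical sigmoids in the Zwietering re-parameterization, so that
(A, μ, λ) appear directly as model parameters:

    logistic      y = A / (1 + exp(4μ/A (λ−t) + 2))
    gompertz      y = A exp(−exp(μe/A (λ−t) + 1))
    gompertz_exp  gompertz + A exp(α (t − t_shift))
    richards      y = A (1 + ν exp(1+ν) exp(μ/A (1+ν)^(1+1/ν) (λ−t)))^(−1/ν)

Fitting is bounded trust-region least squares (`scipy.optimize.
least_squares`) with reproducible heuristic starts: A₀ = max(y), μ₀ = the
largest finite difference quotient, λ₀ = the tangent intercept at that
point, ν₀ = 1, α₀ = 0.01, t_shift₀ = the last time point. Bounds: ν ∈
[0.05, 20] (ν → 0 is the Gompertz limit; the lower bound is numerical),
α > 0 and t_shift within the observed window — the secondary exponential
term describes a second ascent inside the measurement and cannot vanish
into plain Gompertz, which keeps the two families distinguishable. λ may
go negative and A may exceed 400; such estimates are *flagged, never
clamped*, because their frequency is itself a diagnostic (near-flat
drifting wells typically extrapolate the lag before the start of the
measurement).

A fit "fails" on non-convergence, non-finite estimates, a rank-deficient
normal matrix, or zero dynamic range in the data (a non-respiring well
identifies no sigmoid). Model selection minimizes the Gaussian
least-squares AIC, `n ln(RSS/n) + 2(p+1)`; ties go to fewer parameters,
then to the fixed model order above. AUC is the composite trapezoid of
the fitted curve on the observed grid.

### Smoothing-spline fitting (`pmkinetics.spline`)

A cubic smoothing spline (`scipy.interpolate.make_smoothing_spline`),
with the penalty chosen by generalized cross-validation by default and
an explicit override available — smoothing selection is the critical
tunable of this method. Curves of exactly 4 points fall back to a
natural interpolating cubic (the smoothing-spline solver needs 5);
fewer than 4 finite points is the only failure mode. Parameters are
read off the fitted function: A = its maximum, μ = the maximum of its
first derivative on a 10×-density uniform grid (earliest argmax on
ties), and λ from the tangent at the steepest point, y_μ = μ(t_μ − λ),
so the tangent identity holds to machine precision by construction.
AUC integrates the fitted spline (not the raw data) by composite
trapezoid over the observed range; a raw-data trapezoid is available as
an option.

The spline is total: every finite curve — flat, biphasic,
artifact-laden — yields parameters. On (near-)flat curves the smoothed
derivative is noise-dominated; μ is then tiny, λ is flagged unreliable,
and the bootstrap reports very broad intervals for both, which is the
correct statement of uncertainty for a non-reaction.

## Uncertainty (`pmkinetics.uncertainty`)

Per-curve confidence intervals are nonparametric bootstrap percentile
intervals (default level 0.95, B = 100, seeded): (t, y) pairs are
resampled with replacement and the estimator is refitted. Spline
refits average tied time points (as classical smoothing-spline fitting
does) and are evaluated over the original time span, so resamples that
miss an endpoint are still measured on the same window; model refits
keep the resampled multiset, because collapsing duplicates discards
resampling weight and demonstrably narrows the intervals. Failed
refits are dropped and counted; above 50% failures the intervals are
flagged unreliable.

Two curves differ detectably in a parameter when their intervals do not
overlap (closed intervals — a shared endpoint is overlap, the
conservative convention); the signed gap between the nearer opposite
limits is the *minimum expectable difference*, a lower bound on the
underlying effect in measurement units. This per-curve workflow applies
no multiplicity adjustment by design: an exploratory PM screen should
surface every candidate difference.

Group-level machinery:

* `group_mean_cis` averages member points and member limits — a quick
  visualization device, explicitly not a test (flagged `mean_of_cis`).
* `simultaneous_mean_differences` is the testing procedure: a one-way
  homoscedastic layout on per-curve point estimates, user-defined
  contrasts of group means (all-pairs and versus-control helpers
  included), and simultaneous intervals using the max-|t| critical
  value over the contrast set. The critical value is obtained by
  seeded Monte Carlo (default 10⁵ draws) from the multivariate t
  implied by the contrasts' correlation matrix, with a Bonferroni
  fallback if that matrix is degenerate. A single contrast reduces to
  the classical pooled two-sample t interval up to Monte-Carlo error;
  simultaneous intervals are never narrower than unadjusted t
  intervals. An interval excluding zero flags a statistically
  detectable difference; its endpoints bound the effect size on the
  measurement scale.

### Known limitation: spline-based intervals for A

A = max of the fitted spline is an extreme-value functional. At high
signal-to-noise the GCV fit retains a small wiggle on the plateau, and
the maximum over a long plateau is biased upward by roughly twice its
own sampling standard deviation. The reference smoothing-spline
implementation in R (`smooth.spline`, GCV default) shows the same
wiggle on identical data, so this is intrinsic to the method, not an
artifact of this implementation. No resampling scheme around the same
fit can see this bias (we evaluated percentile, basic and
bias-corrected intervals under pair, residual and parametric-residual
resampling, and pilot oversmoothing), so spline-method intervals for A
should be read as describing reproducibility of the estimate, not
calibrated coverage of the true maximum. Where calibrated coverage of
A matters and a parametric family is credible, bootstrap the model fit
(`method="model"`); its A is a regular estimator and its intervals are
well calibrated (≈93–95% empirical coverage in our simulations).

## Shape post-processing (`pmkinetics.shapes`)

* Reaction calls: A > 100 OmniLog units ⇒ positive, else negative (the
  threshold is partially arbitrary by construction and configurable);
  missing A yields no call.
* λ truncation: with M = max(λ), values below −M are set to −M.
  Near-flat drifting wells can put the lag hundreds of hours before
  the measurement; truncation symmetrizes the distribution without
  changing signs. Idempotent by construction.
* Archetypal analysis: observations X (n × 4 parameter vectors) are
  approximated by convex combinations of k archetypes Z that are
  themselves convex combinations of observations: minimize
  ‖X − C·Z‖², C rows on the simplex, Z = B·X with B rows on the
  simplex. Columns are standardized to zero mean/unit variance before
  fitting (the parameters span hours to unit·hours scales) and
  archetypes are reported back in original units; RSS is reported on
  the fitting scale. The alternating algorithm solves the convex
  subproblems by nonnegative least squares with a sum-to-one penalty
  row (weight 200); iteration stops on relative RSS improvement below
  `tol` or on any uphill step (the penalty approximation can produce a
  marginal one), so the recorded RSS trace is non-increasing. k = 1
  recovers the column mean analytically.
* Number of shape classes: archetypes are refitted for k = 1…10 with
  5 random simplex starts each (best-of-restarts RSS kept), and the
  elbow criterion picks the k whose RSS drop is largest *relative to
  the largest subsequent drop* (the last k has no subsequent drops and
  is excluded; a noise-floor clamp keeps flat scree tails from
  producing spurious ratios). On data with planted vertex structure
  this lands on the last big step before the scree flattens — an
  absolute-drop rule would instead always pick the first big step,
  which contradicts the intended reading of "largest step towards a
  lower RSS compared to subsequent improvements".
* Correlations: all-against-all Spearman and Kendall rank correlations
  across the 4+4 parameter columns of both fitting methods
  (distribution-free; the parameters are not normally distributed and
  relations are not linear). Rows with any missing cell are dropped;
  constant columns report NaN.

## Synthetic data (`pmkinetics.synthetic`)

The generator emulates the structure of real PM production runs:

* Designs: strains × biological replicates × technical replicates × 96
  wells, or a cultivation-duration series with per-duration replicate
  counts. Built-in constructors reproduce the reference designs:
  4 strains × 2 biological × 10 technical × 96 = 7680 curves (80
  plates), a single run of 3840, and 1 strain × 9 durations ×
  (4,…,4,2) technical × 96 = 3264 curves with 864 replicate groups.
* Default grid: 0–91 h in 0.25 h steps (365 readings), the
  instrument's 15-minute sampling.
* Shape taxonomy: sigmoid positives (logistic / Gompertz / Richards),
  biphasic curves (sum of two logistic phases — steep ascent, interim
  plateau, shallower second ascent), near-flat negatives with slight
  linear drift, flat negatives, plus injected transient spikes and
  short dips. Values are truncated to [0, 400].
* Noise: additive i.i.d. Gaussian, default σ = 3 OmniLog units —
  chosen once as a realistic magnitude for visually smooth but clearly
  noisy traces on a 0–400 scale; configurable per `ShapeSpec`, with a
  heavier-tailed option (`noise_df`: Student t rescaled to the same
  standard deviation).
* Determinism: a single seed drives a `SeedSequence` spawn per curve
  slot, so identical (design, policy, seed) reproduce identical plates
  bit-for-bit while replicate curves share their true shape with
  independent noise.

What the generator does **not** emulate: autocorrelated or
heteroscedastic noise, plate-position and edge effects, batch drift
between biological replicates, and chemistry-specific false positives.
Passing tests therefore demonstrate correctness of the estimation and
inference machinery under the stated noise model, not robustness to
every artifact of real instrument data.

## Problem sizes and numerical choices

Simulation-based checks use deliberately chosen problem sizes: spline
totality runs over a full 3840-curve production run on the 365-point
grid; bootstrap-coverage and null-size studies use 200 Monte-Carlo
replications at B = 100 on a 1.5-h sampling grid (62 points over 91 h),
which preserves the curve geometry at a fraction of the cost; family
selection uses 20 low-noise (σ = 1) replicates, where the fixed
approximation bias between families dominates the noise and selection
is identifiable. Tolerances follow the estimator class: 10⁻³ relative
for noiseless model recovery, 2% for noiseless spline recovery
(smoothing bias), machine precision for the tangent identity, 10⁻⁸ for
simplex constraints. Degenerate inputs are handled explicitly: flat
curves (no MidTime crossing / no dynamic range), series shorter than
48 reads, curves with fewer than 4 finite points, constant columns in
correlation tables, empty groups, contrast rows not summing to zero.

## Known limitations

* The native algorithm follows the published description of the vendor
  software, not its binary; byte-level parity with the closed-source
  implementation is not claimed.
* The spline's default GCV smoothing can undersmooth at high
  signal-to-noise (see the interval limitation above) and overfit
  near-flat curves; both are visible as broad λ/μ intervals rather
  than hidden.
* No mixed-effects pooling across replicate bundles and no common
  spline over a bundle of repetitions; each curve is fitted alone.
* No monotone or shape-constrained spline variants.
* Group comparisons assume a homoscedastic one-way layout on per-curve
  point estimates and ignore the within-curve estimation error carried
  by the per-curve intervals.
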