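# Methods

## The model

`proteintraj` models longitudinal concentrations of the two major drug-binding
plasma proteins — serum albumin (g/L) and alpha1-acid glycoprotein, AAG
(mg/dL) — as a function of time in two regimes: gestational age (weeks, from
20 weeks onward) and postpartum duration (weeks, 0 = delivery).  The core is a
location–scale(–shape) distributional regression

    y_i ~ F( m(t_i), sigma(t_i), theta ),

where the location `m(t)` is a penalized B-spline (P-spline) in time, the
scale is constant, piecewise constant (split at a breakpoint, default 0.5
weeks postpartum), or log-linear in time, and `F` is one of three error
families:

* **normal** — the baseline;
* **two-component normal mixture** — components written as offsets from a
  shared location with the identifiability constraint
  `w1*o1 + (1-w1)*o2 = 0`, so the location parameter *is* the arithmetic
  mean and the spline regresses the mean directly;
* **two-piece (split) normal**, often labelled skew-normal type 2 — the
  Fernandez–Steel parameterization with side-dependent scale around the mode:
  `f(y) = c*phi(nu*(y-mu)/sigma)` below the mode and
  `c*phi((y-mu)/(nu*sigma))` above it, `c = 2/(sigma*(nu+1/nu))`.  `nu < 1`
  gives a left skew.  This parameterization was chosen because the CDF,
  quantile function and mean all have closed forms
  (`E[Y] = mu + sigma*sqrt(2/pi)*(nu - 1/nu)`) and it reduces exactly to the
  normal at `nu = 1`.

Observations are treated as independent.  Most subjects in the emulated study
contribute at most two samples, which is why no random-effect structure is
modelled; with strongly longitudinal data the quantile curves would be
anti-conservative.

## Fitting

Fitting alternates (a) a penalized weighted least-squares update of the
location spline given the current scale/shape — with EM responsibilities
supplying the weights and working response for the mixture — and (b) closed-
form or one-dimensional maximum-likelihood updates of scale and shape given
the location.  Iteration stops when the relative change in penalized
log-likelihood drops below 1e-8 (cap: 500 iterations); non-convergence is
reported on the fitted object, never raised.  A step-halving safeguard keeps
the penalized log-likelihood non-decreasing; the mixture uses 5 seeded
restarts (one from a residual-quantile split, the rest random) and keeps the
best penalized likelihood.  Scales are floored at `1e-6` of the data SD to
prevent degenerate spikes.

The smoothing weight lambda is selected once, on a preliminary Gaussian fit,
by minimizing the generalized AIC `n*log(RSS/n) + k*edf` over a 41-point log
grid on [1e-4, 1e8] with golden-section refinement, and is then held fixed
through the family iteration.  Re-selecting lambda inside the loop would
couple the penalty to the working weights and break the monotonicity
guarantee; in practice the Gaussian choice is already near-optimal for the
other families because the location model is shared.  Ties in GAIC resolve to
the larger lambda (the smoother fit); the RSS entering GAIC is floored at
1e-12 of the total sum of squares so that numerically perfect fits tie and
the tie rule applies.

P-spline defaults: cubic basis, 20 equally spaced interior knots over the
observed time range (fewer when there are fewer distinct times), order-2
difference penalty.  The knot grid extends past the domain without boundary
clamping, so straight lines lie exactly in the order-2 penalty null space.
The penalized system is solved in augmented least-squares form, which stays
accurate even at lambda ~ 1e12.  Effective degrees of freedom (edf) are the
trace of the smoother hat matrix, recomputed at the final working weights;
total model edf adds the free scale (1–2) and shape (1 for the skew, 4 for
the mixture) parameters.

Model choice uses `GAIC = -2*loglik + k*edf` with `k = 2` by default.  A more
complex candidate displaces a simpler one only if its GAIC advantage exceeds
`delta` (default 2.034): small AIC differences are judged too minute to
justify extra structure, and the threshold is user-configurable.

For AAG the data are far too sparse (<40 samples per cohort) to discriminate
error families or variance structure, so the analysis is restricted to the
central tendency: a natural cubic smoothing spline with the smoothing
parameter chosen by generalized cross-validation (leave-one-out CV available
behind a flag), duplicate times averaged with multiplicity weights.  The
pipeline's AAG runs use a Gaussian constant-variance smoother for the same
reason.  No smoother extrapolates; evaluation outside the fitted time range
is an error rather than a silent extension.

## Validation

Quantile curves evaluate the family quantile at the local location/scale/
shape along a time grid (default percentiles 2.5, 10, 25, 50, 75, 90, 97.5).
Coverage concordance compares each observation with the model quantile at its
own time and reports the percent strictly below; a value exactly on the curve
counts as not-below (ties are measure-zero under these continuous families).
Goodness of fit uses normalized quantile residuals
`r_i = Phi^{-1}(F(y_i | t_i))`, which are standard normal under a correct
model; the summary statistic is their Kolmogorov–Smirnov distance from
N(0, 1).  CDF values at machine 0/1 are clamped with a warning.  Albumin
records above a threshold (default 60 g/L, implausibly high) are excluded
before fitting and the count reported.

## Computational functions

The exported deliverable per analyte/period is a small parametric bundle a
PBPK platform can evaluate directly: (1) a mean polynomial, fit by least
squares on a 0.1-week grid with the degree increased from 1 until R² against
the nonparametric curve exceeds 0.995 (cap 10, with explicit failure rather
than silent oscillation); (2) a quantile function that converts the
polynomial mean to the family location (identity for normal and the
constrained mixture; subtracting the closed-form mean–mode offset for the
two-piece) and applies the family quantile; (3) a seeded sampler drawing
(time, concentration) pairs for virtual populations.  Bundles round-trip
through schema-versioned JSON and embed the pipeline seed, so a run is
reproducible byte for byte.

A caveat on the R² rule: R² is a variance-explained criterion, not a sup-norm
bound.  For the slowly varying gestational curve the first accepted
polynomial also tracks the curve to well under 2% of its range, but for the
postpartum curve — a steep exponential rise out of delivery — the first
polynomial past R² = 0.995 can still miss the delivery endpoint by ~1 g/L.
Users who care about the boundary should raise `r2_threshold`.

## Synthetic data

The generator emulates the structure of the motivating perinatal cohort
study, whose raw data are access-restricted: ~380 pregnant subjects / ~870
albumin samples over 20–42 weeks gestation; ~354 postpartum subjects / ~780
samples over 0–46 weeks (visit windows 20–26 and 30–38 weeks plus delivery;
postpartum 2–24 weeks with a delayed tail to 46 and a point mass at t = 0);
~30 subjects and ~35 samples per AAG cohort; a samples-per-subject profile
with ≥65% of subjects contributing at most two samples; and a configurable
count of injected >60 g/L albumin outliers (default one per albumin cohort).

True mean curves pass exactly through the published anchor values: albumin
linear from (20 wk, 34.3) to (37 wk, 33.4) g/L in gestation; postpartum
`42.3 - 10.7*exp(-k t)` with `k = ln(10.7/4)/3 ≈ 0.328` so the curve hits
31.6 g/L at delivery, 38.3 g/L at 3 weeks and the 42.3 g/L plateau; AAG
linear from (24 wk, 53.6) to (37 wk, 44.9) mg/dL and from (2 wk, 120.4) to
(12 wk, 74.7) mg/dL.  The exponential-saturation form for the postpartum rise
is a generator choice fitting three anchors, not a claim about the underlying
spline.  Noise uses the published family structure — a normal mixture in
gestation, a left-skewed two-piece normal postpartum with piecewise SD 4.86
g/L (≤0.5 wk) / 3.64 g/L (>0.5 wk) — with unprinted shape values declared as
defaults (mixture weight 0.8, offsets +0.9/−3.6 g/L, component SDs 2.5/5.0
g/L; skew nu = 0.8; AAG SDs 15/25 mg/dL) and flagged `not_from_source` in the
preset metadata.  Non-positive far-tail draws are redrawn.  What the
generator does *not* emulate: within-subject correlation, covariates
(race, weight, country), assay error structure — so passing tests demonstrate
correctness of the machinery under the stated model, not robustness to those
real-data features.

## Problem sizes and numerical choices

Recovery and calibration checks run at n ≈ 800 with 10–20 seeded replicates,
the size of the emulated albumin cohorts.  Quantile inversion for the mixture
uses bracketed root finding to 1e-10 in probability (bracket: component means
± 10 max SDs, widened as needed).  All samplers take an explicit seed; there
is no global RNG state.  Exported artifacts are plain CSV/JSON with no
wall-clock timestamp, so identical seeds reproduce identical bytes.

## Known limitations

* Independence is assumed; repeated measures mildly understate uncertainty.
* The AAG smoothing splines are effectively linear at these sample sizes —
  the roughness penalty dominates — and should be read as preliminary trends.
* The piecewise-variance breakpoint (0.5 weeks postpartum) is taken as given,
  not estimated.
* Reference equations for comparison cohorts are user-supplied configuration;
  the package ships only their printed point evaluations as validation
  fixtures and never invents coefficients.
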