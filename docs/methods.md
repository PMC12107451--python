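# Methods notes

## Scope and pipeline

The package estimates weight-gain-for-gestational-age reference charts
from longitudinal antenatal weights, standardizes each pregnancy's total
gestational weight gain (GWG) against them, and relates the resulting
Z-score groups to adverse pregnancy outcomes within baseline-BMI strata.
The stages are: visit validation → population selection → per-cohort
mixed-model chart estimation on a reference subpopulation → Z-scoring of
the full study population → multiple imputation → modified-Poisson risk
models → Rubin pooling.  A synthetic-data generator with retained ground
truth exercises every stage.

## Selection rules

A visit is invalid when the weight change from baseline is more extreme
than −4 kg or +19 kg; the bounds themselves are valid ("more extreme
than" reads as strict exceedance) and only the visit is discarded, never
the woman's other visits.  The study population keeps singleton
pregnancies with ≥2 valid weights, known delivery gestational age and
neonatal vital status, and delivery ≤42 weeks; exclusions are counted
against the first rule failed so category counts always sum to the total
excluded.  The chart-fitting reference subpopulation further excludes,
hierarchically: first valid weight after 20 weeks, preterm delivery
(<37 weeks), stillbirth.  Hierarchical (first-match) attribution was
chosen because it makes the per-category counts mutually exclusive and
additive, which is what a selection flow chart reports.

## Transform and reference model

Gains are modelled as `y = ln(gwg + 5)`; the +5 kg shift makes early-
pregnancy losses (bounded below by the −4 kg validity rule) positive
before the log, and the log removes the right skew of later gains.  The
per-cohort model is a linear mixed model with a woman-level random
intercept; gestational age enters through a restricted quadratic spline
(RQS) with four knots at the 5th/35th/65th/95th percentiles of the
cohort's visit gestational ages, plus BMI-group main effects and
BMI × linear-GA interactions.  Parameters that matter:

- **Knot placement** — percentile knots adapt to each cohort's visit
  schedule; the linear-interpolation quantile definition is used (other
  definitions move knots by well under a week at realistic sizes).
- **RQS form** — quadratic truncated-power terms re-expressed so every
  basis function, and hence any fitted curve, is linear beyond the
  *last* knot only (the convention in epidemiological trend analysis;
  restricting both tails is a different basis and deliberately not
  implemented).
- **Estimation** — REML, so the variance components that set the chart
  SD are unbiased; fitting is delegated to `statsmodels.MixedLM`.  When
  the residual variance is numerically zero (noise-free simulated data)
  the mixed model is degenerate and the fixed effects are recovered by
  least squares with both components reported as zero.
- **Chart SD** — `sd_log = sqrt(σ_b² + σ_e²)`, constant across weeks
  because the fitted components are homoscedastic.  The chart schema
  still carries an SD column per week so heteroscedastic extensions can
  slot in without changing consumers.
- **Percentiles** — normal quantiles on the transformed scale,
  back-transformed: the shift-log transform is chosen precisely to make
  transformed gains near-normal, so this is the natural reading.  The
  round-trip identity (standardizing the chart's percentile p returns
  Φ⁻¹(p)) holds to machine precision by construction and is asserted in
  tests.
- **Grid** — integer weeks 8–42, covering enrolment-to-delivery support;
  extrapolation outside the grid is refused rather than clamped.

Z-scores standardize on the transformed scale by default (matching the
model's normality); a kg-scale option exists for external standards
published as kg means/SDs.  Chart lookup uses the nearest integer week
(charts are published per week); linear interpolation is available
behind a flag.  Quartile cut-offs use full-precision ±0.674490
internally and are displayed as ±0.67.

## Guideline adequacy and external standards

The adequacy ratio divides observed total gain by a guideline
recommendation assembled from printed constants: first-trimester
allowance (2 kg underweight/normal, 0.5 kg overweight/obese) plus a
BMI-specific weekly rate (0.51/0.42/0.28/0.22 kg/wk) times weeks beyond
13.  Published external weight-gain standards are *not* embedded; they
enter through a plugin interface (`ExternalStandard`) declaring a
gestational-age support and a per-week mean/SD, so their coefficients
remain with their publishers.

## Imputation and pooling

Missing covariates and outcomes are imputed by fully-conditional
chained equations: Bayesian linear draws for continuous variables,
logistic draws (with an observed-frequency fallback on separation) for
binaries, a handful of cycles per copy, independent chains per copy,
all driven by one seed.  A joint-MCMC imputer would be an equally valid
engine; chained equations was chosen for transparency and testability.
Default m = 50; the orchestrated pipeline and tests use smaller m since
pooled points stabilize quickly at the simulated missingness rates.
Pooling is exactly Rubin: point = mean, T = W + (1 + 1/m)B, with risk
ratios pooled on the log scale where the normal approximation holds.
With complete data the pipeline collapses to a single fit rather than m
identical copies.

## Outcome models

Modified Poisson regression — log-link Poisson working model on the
binary outcome with an HC1 sandwich variance, one record per pregnancy —
returns risk ratios directly and equals the closed-form ratio of
proportions on saturated designs (asserted exactly in tests).  The
reference exposure group is G3 (51st–75th percentile), printed as RR = 1
exactly.  Continuous adjustment covariates (maternal age, enrolment GA,
height, BMI; plus parity and prior preterm birth as binaries) enter via
3-equally-spaced-knot RQS.  Covariates that are constant within a
stratum or sensitivity subset are dropped from the design rather than
producing a singular fit.  Adjusted risks use marginal standardization
(average prediction with the group set counterfactually) with
delta-method CIs; log-link predictions above 1 are flagged in
diagnostics, never silently clipped.  Groups with zero events are
reported with undefined RRs and a diagnostic rather than a divergent
fit.  Dose-response curves come from marginal logistic GEE
(independence working correlation) with the continuous Z splined,
followed by a lowess smoother of predicted probabilities evaluated on a
fixed Z grid.  Baseline-characteristic associations with Z use marginal
linear models with cohort-clustered robust SEs (falling back to HC1
with a warning when only one cohort exists).

## Synthetic cohorts

The generator emulates: five cohorts, enrolment before 25 weeks
(truncated-normal, median ≈ 13 weeks), follow-up weights at stochastic
4–6-week gaps truncated at delivery, a BMI mix of 23/60/13.4/3.6%
across underweight/normal/overweight/obese, and a decelerating
quadratic mean transformed-gain curve calibrated so the median total
gain at 39 weeks is ≈ 7 kg, with mild cohort- and BMI-specific
intercept/slope offsets.  Default variance components are
σ_b = 0.10, σ_e = 0.08 on the transformed scale.  Outcome risks are
log-linear in a latent standardized gain Z (or piecewise-constant in
its quartile group when a direct group-risk table is configured, which
makes end-to-end risk-ratio recovery exact by design).  The latent Z
uses the residual *reserved for the final visit*, so the realized
Z-score computed downstream estimates the latent one up to chart
estimation error and week rounding — a deliberate choice that separates
pipeline error from irreducible exposure misclassification.  Because
gains are generated on the transformed scale, the +5 kg shift is
invertible by construction.  Missingness injection supports MCAR and
MAR-on-observables (masking probability proportional to a logistic
function of an observed driver, renormalized to the target marginal
rate).

What the generator does **not** emulate: digit preference and device
error in weights, gestational-age dating error, visit schedules tied to
risk (informative follow-up), twin pregnancies, time-varying covariates,
or heteroscedastic gain variance over gestation.  Passing tests
therefore demonstrate the pipeline's correctness under its stated
model, not robustness to those real-data features.

## Problem sizes in tests and the acceptance script

Simulation-based checks use sizes chosen to make Monte-Carlo error
small relative to their tolerances: 4 000 women for chart/self-
standardization properties, 3 000 for single-cohort variance-component
recovery, 5 000 × 300 replicates for sandwich-CI coverage, and a 30 000-
woman five-cohort run for end-to-end recovery of a configured risk
ratio of 1.6.  All are seeded and deterministic.

## Known limitations

- The chart SD is constant in gestational age under the default model;
  populations with strongly fanning gain distributions need the
  heteroscedastic extension.
- Marginal standardization CIs use the delta method; a bootstrap would
  be preferable for very small strata (the obese stratum at realistic
  sizes).
- The imputation engine assumes roughly linear/logistic conditional
  models; heavily non-normal continuous variables should be transformed
  before imputation.
- Modified Poisson can predict risks above 1 for extreme covariate
  combinations; these are surfaced as diagnostics and indicate the
  log-link approximation is strained in that stratum.
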