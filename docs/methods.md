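# Methods

This note documents the statistical model behind each certscore component,
the defaults and why they were chosen, and what the synthetic cohort can and
cannot tell you about real data.

## Quartile-point scoring

A score component is a lipid concentration or a ratio of two lipids. For a
scoring cohort the package fits the 25th/50th/75th percentiles per component
(numpy's linear interpolation between order statistics; the convention is
configurable via any numpy percentile method) and assigns quartile
membership with half-open intervals closed on the left cut — a value exactly
at a cut falls in the *lower* quartile. Ties are therefore resolved
conservatively (fewer points). All-tied components produce flagged
degenerate boundaries rather than an error, so constant assay channels
surface in the audit output instead of aborting a run.

CERT1 awards (0, 0, 1, 2) points across quartiles over six ceramide
components, CERT2 awards (0, 1, 2, 3) over four components; both cap at
6×2 = 4×3 = 12. Risk-category bands are configurable; the defaults
(CERT1: 0–2 / 3–6 / 7–9 / 10–12, CERT2: 0–3 / 4–6 / 7–8 / 9–12) follow the
published score literature because band edges are a reporting convention,
not a property of the data. Two boundary sources exist: `cohort_internal`
(fitted on the cohort being scored — appropriate for population studies)
and `external_reference` (frozen cut-points — required for clinical scoring,
where boundaries must not drift with the sample at hand). Missing lipids
exclude a subject (complete-case) with a reported count; no imputation.

## Association models

**Prevalent hypertension** is classified as BP-lowering treatment or
SBP ≥ 140 mmHg or DBP ≥ 90 mmHg (thresholds inclusive) and modelled by
maximum-likelihood logistic regression (statsmodels). **New-onset
hypertension** is modelled by Cox proportional hazards (lifelines) with
attained age as the timescale: entry at baseline age, exit at the age of
onset or censoring, which handles left truncation exactly; sex is a
stratifying variable in every Cox fit (including the "unadjusted" one), and
ties use the Efron approximation. The age+sex adjustment set (M1) is not
fitted in the Cox family — age is the time axis and sex the stratum, so the
model would be vacuous.

CERT totals enter as raw points (effects are per score point). Lipid species
and ratios are standardized to zero mean and unit SD (sample SD, ddof 1)
before fitting, so their effects are per SD; a log-transform switch is
available for analysts who prefer effects per log-unit. Confidence intervals
are Wald on the log-odds/log-hazard scale (±1.96 SE, exponentiated).
Complete separation and non-convergence raise a diagnostic error rather than
returning silent estimates. No multiple-testing correction is applied; the
`significant` flag marks raw p < 0.05. Sex-stratified refits and a
sex×predictor Wald interaction test are available as suite options.

## Risk curves

Lipid predictors are winsorized at the 1st/99th percentiles before
smoothing. The cut-points are *nearest order statistics* (the order
statistic at the floor of the lower rank and the ceiling of the upper rank)
rather than interpolated percentiles: clipping then never moves the
cut-defining order statistics, which makes winsorization exactly idempotent
— an interpolated cut recomputed on clipped data drifts outward slightly, so
repeated application would keep nudging the extremes.

The smoother is loess: at each of 100 evenly spaced grid points across the
winsorized range, a weighted polynomial (degree 2, tricube weights over the
nearest 75% of observations) is fitted and its intercept taken as the risk
estimate. The 95% band is pointwise normal, `fit ± 1.96·s·‖l‖`, where `l` is
the equivalent kernel at the grid point and `s²` the residual variance of
the smooth. Fitting the binary outcome directly (rather than model
residuals) makes the curve an estimate of P(outcome | predictor). Two
numerical caveats are intrinsic to the method: quadratic local fits can
overshoot slightly at sharp transitions (so a fitted "risk" may exit [0,1]
near a step, and the curve is not guaranteed monotone even for monotone
truths — local-linear fits, `degree=1`, are monotone on a noise-free step),
and grid points at the boundary of a sparse predictor tail carry wide bands.

## Synthetic cohort generator

The generator emulates a stratified population survey of adults aged 25–74
with ~46% men, calibrated to the baseline characteristics of the
hypertension-free stratum of a Finnish risk-factor survey (age 46.7 ± 12.9 y,
BMI 26.5 ± 4.5 kg/m², TC 5.6 ± 1.1 mmol/L, HDL 1.5 ± 0.4, TG 1.4 ± 0.9,
CRP 2.4 ± 4.9 mg/dL, smoking 26.9%, diabetes 4.2%, lipid-lowering treatment
5.2%). Design choices, each configurable:

* **Lipids** are multivariate log-normal — concentrations are positive and
  right-skewed and a Gaussian copula on the log scale is the simplest joint
  model with specified marginals and correlation. Default correlation: 0.4
  within lipid class, 0.2 across classes. Default geometric means are
  typical plasma concentrations (e.g. Cer(16:0) ≈ 0.22, Cer(24:0) ≈ 2.6 in a
  common fixed unit) with log-SD 0.35.
* **Continuous covariates** are truncated normals whose location is solved
  so the *post-truncation* mean equals the configured mean (plain truncation
  would bias, e.g., mean age by +0.7 y); TG and CRP are log-normal with
  matched mean/SD. The truncation necessarily shrinks the realised SD below
  the configured value. LDL (3.4 ± 0.9 mmol/L) is not part of the published
  baseline table; the default is Friedewald-consistent with the TC/HDL/TG
  means.
* **Prevalent hypertension** is Bernoulli from a logistic model; the default
  linear predictor uses age (0.075/y), male sex (0.20), BMI (0.10/unit) and
  the CERT2 total (0.10/point), with the intercept (−9.26) calibrated so the
  overall prevalence is ≈ 11.3%.
* **Blood pressure** is drawn *conditionally on* prevalent status (treated
  fraction 90.6% among the prevalent; untreated prevalent subjects are
  forced above the SBP threshold; the non-prevalent are truncated below both
  thresholds), so the clinical threshold rule reproduces the simulated
  indicator by construction, and SBP > DBP > 0 always holds.
* **New-onset hypertension** (among the prevalent-free) uses a Weibull
  baseline hazard on the age axis, H₀(a) = (a/scale)^shape with shape 5 —
  onset risk rising steeply with age — and closed-form conditional sampling
  given onset-free survival to baseline age. The scale (109.5 y) is
  calibrated so ≈ 18% of the prevalent-free develop hypertension within the
  10-year follow-up under the default effect sizes (BMI 0.06, smoking 0.15,
  CERT2 0.08 per point on the log-hazard). Death is independent exponential
  censoring at 0.0097/person-year; competing-risk structure is deliberately
  not modelled.
* **Reproducibility**: one master seed; per-block substreams derived with
  `SeedSequence.spawn`, so identical configs give byte-identical cohorts and
  adding a variable block cannot perturb earlier draws.

What the simulator does *not* emulate: survey sampling weights and regional
stratification, registry linkage and treatment-initiation dynamics,
age-dependence of lipid levels, correlation between covariates (BMI and
waist are drawn independently), measurement error in BP or assays, and
informative censoring. Passing tests therefore demonstrate that the
*analysis machinery* is correct and calibrated under a known generative
model — not that the effect estimates from any real cohort would be
reproduced.

## Verification strategy and problem sizes

Every estimator is checked against an independent oracle on small problems:
the logistic engine against the 2×2 cross-product ratio (relative tolerance
1e-6), the Cox engine against grid-search maximisation of the left-truncated
partial likelihood on ≤ 5 subjects (absolute tolerance 1e-3 on the log-HR),
quantiles and winsorization against brute-force sorted-list constructions,
and the loess smoother against flat, step and linear truths. Frequentist
calibration is demonstrated by a 50-seed simulation study at n = 20 000 per
seed: the 95% Wald CIs of both model families must cover the generator's
per-point effect in ≥ 90% of seeds (observed ≈ 92–94%). These sizes keep the
full verification run at about a minute on a single core while leaving the
Monte-Carlo error of the coverage estimate (≈ 3 percentage points) well
inside the acceptance margin.

## Known limitations

* The loess band is a normal approximation with a global residual-variance
  estimate; it is not clamped to [0,1] and is anti-conservative in sparse
  tails.
* The Cox implementation requires at least one event per sex stratum and
  refuses zero-event strata with an explicit error.
* Quartile boundaries from `cohort_internal` scoring drift with the input
  sample; frozen `external_reference` boundaries are the right mode for any
  comparative or clinical use.
* The generator's outcome models use the CERT totals themselves as the
  risk-driving exposure; analyses of single lipids on simulated data thus
  see attenuated, score-mediated effects rather than direct lipid effects.
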