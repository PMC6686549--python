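# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic-data validation does and does
not establish.

## Analysis model and effect decomposition

One analysis row per mother–child pair: exposure `A` = continuous
pre-pregnancy BMI (kg/m², self-reported height/weight), mediator `M` =
excessive gestational weight gain (binary), outcome `Y` = child
BMI-for-age z-score from the last height–weight pair recorded between 48
and 59 months, covariates `C` = race (4 levels), education (4 levels, an
SES proxy), gestational diabetes, smoking during pregnancy, and an
enrolment-period indicator. The mediator model is logistic, the outcome
model linear with an exposure-by-mediator interaction (`interaction:
false` drops it). The extended covariate set for the sensitivity
analysis adds maternal age at delivery, cesarean delivery, gestational
age (weeks), infant sex, birth weight (kg) and parity.

With `p(a) = expit(β₀ + β₁a + β₂ᵀc)` the decomposition at a vs a\*
(default 30 vs 22) is

    CDE(m) = (θ₁ + θ₃ m)(a − a*)
    NDE    = (θ₁ + θ₃ p(a*))(a − a*)
    NIE    = (θ₂ + θ₃ a)(p(a) − p(a*))
    TE     = NDE + NIE,   PM = NIE / TE

the standard product-method decomposition for a continuous outcome and
binary mediator under the usual no-unmeasured-confounding assumptions.
TE = NDE + NIE holds exactly by construction on every fit and every
bootstrap replicate. A Monte-Carlo oracle
(`mc_counterfactual_oracle`) simulates the potential outcomes
`M(a) ~ Bernoulli(p(a))`, `Y(a, m)` directly and is used in tests as an
independent check of the closed form; outcome residual noise cancels in
expectation and is omitted by default (a test verifies that including it
changes nothing beyond MC error).

**Conditioning.** Effects are conditional on a covariate vector `c`,
by default the sample means of the dummy-coded covariate columns.
`Contrast(conditioning="marginal")` instead averages the mediator
probabilities over the empirical covariate rows; with modest covariate
effects the two agree closely because `expit` is nearly linear over the
covariate spread. The CDE's mediator level defaults to m = 0 (no
excessive gain).

**Inference.** Nonparametric bootstrap, B = 1000 by default, percentile
intervals. Resamples whose fits fail (constant mediator, separation,
rank deficiency) are dropped and counted; more than 10% failures raises
an error instead of returning unreliable intervals. PM intervals use the
bootstrap distribution of NIE/TE, dropping (and counting) replicates
whose TE changes sign relative to the point estimate.

**Logistic fitting** is Newton–Raphson IRLS with a 50-iteration cap,
covariance from the inverse observed information, and explicit
divergence/separation detection. It matches statsmodels' MLE to 1e-6 in
the test suite. The OLS outcome fit reports rank-deficiency with the
offending columns (QR with pivoting).

## Growth cleaning

Child height series should be non-decreasing. A value at index i > 0
departs when it falls below the running maximum of the earlier values by
more than the tolerance (default 0 cm; ties are not departures). Flagged
and missing values are re-imputed as

    w_ln · LastNext + w_fr · regression,   defaults (0.3, 0.7)

where LastNext is the mean of the nearest usable neighbours and the
regression is an OLS line through the child's usable (age, height)
points. The weights follow the listing order of the two methods in the
source procedure, which does not say which weight attaches to which
method; both are configurable. Flagged points are excluded from the
regression fit. Replacement is iterated (≤ 10 passes) until re-flagging
finds nothing; a pathological series that still departs afterwards is
clamped to the running maximum so the output always satisfies the rule.
Only height is cleaned — child weight may legitimately decrease. Cleaning
is idempotent and leaves unflagged values bit-identical.

## Anthropometry

BMI-for-age z-scores use the LMS transform, `z = ((x/M)^L − 1)/(L·S)`,
with the analytic log-limit branch for |L| ≤ 1e-8. L, M and S are
linearly interpolated between tabulated ages (the source analysis used
monthly reference tables without stating its interpolation; tests verify
continuity of z in age). Tables are read in the CDC growth-chart CSV
dialect (Sex 1/2, Agemos, L, M, S); a smooth synthetic reference
covering 18–84 months ships with the package so nothing need be
downloaded — it is shaped like a pediatric BMI reference but is not the
CDC 2000 reference and must not be used for clinical work.

Child categories from z: underweight < 5th percentile ≤ normal < 85th ≤
overweight < 95th ≤ obese, with percentiles mapped to z-cutoffs through
the standard normal quantile. Maternal categories: normal [18.5, 25),
overweight [25, 30), obese ≥ 30; BMI < 18.5 signals exclusion. GWG is
(delivery weight − LMP weight)/0.45359237 lbs, set missing when the last
weight predates delivery by more than 7 days. IOM adequacy ranges
(lbs): 25–35 normal, 15–25 overweight, 11–20 obese, treated as closed
intervals (boundary gains are adequate — the conservative reading of
ranges stated without boundary semantics); the mediator is 1 iff
excessive. The source also lists 28–40 lbs for underweight women —
apparently swapped with the conventional normal-weight range; it is
carried in config for completeness, unused because underweight mothers
are excluded, and deliberately not "corrected".

## Synthetic cohort generator

The generator inverts exactly the model pair the analysis fits, so every
estimator can be checked against known truth.

- **Exposure:** 3-component normal mixture truncated at 18.5, weights
  (0.45, 0.21, 0.34), means (21.9, 27.2, 34.6), SDs (1.7, 1.35, 4.2)
  kg/m² — calibrated so the maternal BMI classes land near 44/25/31%
  normal/overweight/obese with mean ≈ 27.4, matching the published
  cohort's composition.
- **Mediator:** β₀ = −1.15, β₁ = 0.06 per BMI unit, small covariate
  effects; marginal excessive-GWG prevalence ≈ 58%.
- **Outcome:** θ₁ = 0.322/8 (so the CDE at the 8-unit contrast is
  0.322), θ₃ and θ₂ solved in closed form so that NDE = 0.235 and
  NIE = 0.020 at the default contrast; σ_y = 0.85 and θ₀ = −0.78 put
  ≈ 24% of children at or above the 85th percentile. The implied truth
  is CDE 0.322, NDE 0.235, NIE 0.020, TE 0.255, PM 7.84%. (The published
  table prints TE 0.246 and PM 8.13%, which is inconsistent with its own
  NDE + NIE = 0.255, presumably rounding/pooling; the package enforces
  exact additivity, so the generating truth carries 0.255.)
- **Covariates** are drawn independently of the exposure by default
  (category probabilities taken from the published cohort's margins); a
  `confounded` switch shifts the BMI distribution by education to let
  tests exercise confounding adjustment — the conditional models remain
  correctly specified, so the truth is unchanged.
- **GWG values** are drawn consistently with the sampled mediator: above
  the IOM upper bound (gamma offset, mean ≈ 8 lbs) when excessive,
  uniform from 8 lbs below the lower bound to the upper bound otherwise,
  which reproduces the observed inadequate/adequate split.
- **Growth records** realise the sampled outcome: visits follow a
  jittered schedule (24–66 months), heights come from a smooth
  increasing stature curve with a per-child offset, and BMI follows the
  constant-z LMS trajectory with small per-visit jitter — except at the
  last visit inside the 48–59-month window, where the z-score is exact,
  so deriving the cohort recovers the generated outcome to machine
  precision (a test asserts 1e-9).
- **Corruption and missingness** are injected as a separate step:
  heights after the first visit are pulled below the previous visit's
  height with probability `glitch_rate` (guaranteeing a detectable
  departure; defaults 0.02), and covariate cells are set missing with
  probabilities that depend on the always-observed cohort-period
  indicator (rate ×1.5 / ×0.5 by period) — MAR given observed data, the
  assumption FCS imputation needs. Defaults: education 6%, smoking 4%,
  gestational diabetes 4%. All altered cells are logged for test
  assertions.

What the generator does **not** emulate: EMR visit processes, sibling
correlation, gestational-age-specific weight-gain trajectories,
measurement error in self-reported weight, or real reference tables.
Passing tests therefore demonstrate correctness of the estimators under
the assumed data-generating model, not robustness to the full messiness
of clinical data.

## Multiple imputation

FCS: initialise missing cells from observed values, then cycle (default
10 sweeps, 20 datasets; both configurable) through the incomplete
variables in order of increasing missingness, regressing each on all
other analysis variables at their current values and redrawing its
missing cells from the fitted conditional. Continuous variables use
linear regression with normal noise and posterior parameter draws
(normal coefficients, scaled inverse-χ² variance); binary variables use
logistic draws with posterior coefficient draws; multi-level
categoricals use a ridged Newton multinomial (softmax) fit with plug-in
parameters — a discriminant-equivalent conditional under the
conditional-model view, with the plug-in step documented as an
approximation that slightly understates between-imputation variance. A
conditional fit that fails falls back to a marginal draw for that sweep
(logged). Covariates only are imputed by default; the exposure, mediator
and outcome are required complete.

Pooling: Rubin's rules (`point = mean`, `T = W + (1 + 1/m)B`, normal
reference) for scalar estimates with variances. For the decomposition
the pipeline bootstraps within each completed dataset and averages the
percentile bounds across imputations (a von Hippel-style choice the
source procedure does not specify); pooled points are the means of the
per-imputation points, which preserves TE additivity exactly, and PM is
recomputed as pooled NIE / pooled TE.

## Table-1 summaries and pipeline

Bivariate comparisons stratify children into normal/underweight vs
overweight/obese: pooled-variance t-tests for continuous variables
(Welch by flag), Pearson χ² without continuity correction for
categorical ones; percents are displayed per-stratum with non-missing
denominators and recomputed from stored counts. `run_study` chains
simulate/ingest → clean → derive → impute → mediate (minimal and
extended covariate sets) → report under a single seed; exclusion
accounting is exact (`rows_in = rows_analyzed + Σ exclusions`) and
no-op stages are flagged in the report.

## Validation sizes and numerical choices

The simulation-based checks use: consistency at n = 50,000 (one seed,
every coefficient within 3 estimated SEs); parameter recovery over 200
seeds at n = 766 (mean NIE within 2 simulation SEs of truth); bootstrap
coverage over 200 replications with B = 200 (NIE interval coverage in
[0.90, 0.98]); MI recovery over 200 seeds at 20% MAR missingness with
m = 5, cycles = 5; calibration over 100 seeds. The oracle-equivalence
battery makes 100 independent 3-MC-SE comparisons at n_mc = 10⁶, so it
allows the statistically expected number of excursions (at most 2, each
within 4 MC-SE) rather than treating a single 3σ fluctuation as failure.

Numerical details: IRLS capped at 50 iterations (tolerance 1e-10 on the
step), divergence beyond |β| > 10³ or fitted-probability separation
raises; imputation conditionals add a 1e-4 ridge and use a 1e-6
tolerance; bootstrap resample seeds derive from the study seed; the LMS
branch switch at |L| = 1e-8 agrees across branches to well below 1e-6;
percentile interval endpoints use linear interpolation (numpy default).

## Limitations

- Effects are conditional on covariate values (or covariate-averaged on
  request); no marginal standardisation over a target population.
- Binary-outcome (odds-ratio scale) decompositions, multiple mediators,
  and exposure-induced mediator–outcome confounding are out of scope, as
  are E-value-style sensitivity analyses.
- The percentile bootstrap slightly undercovers at n = 766 (observed
  ≈ 0.94–0.95 for the NIE), as expected for mildly skewed estimators.
- The shipped LMS reference is synthetic; supply a real reference CSV
  for any substantive use.
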