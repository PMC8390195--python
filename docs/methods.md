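# Methods

## Outcome and predictors

The outcome throughout is the per-patient ALSFRS-R slope (pt/month), the
OLS regression coefficient of the 0–48 sum score on visit time in months.
Slopes are signed (negative = decline).  Observational-cohort slopes use
time since symptom onset as the regressor when the visits carry it; trial
slopes use trial time.  Since a per-patient constant time shift leaves the
OLS slope unchanged, the two conventions differ only in the intercept.  No
synthetic (0, 48) anchor at onset is added: only measured scores enter the
fit (configurable at the call level by supplying the anchor as a visit).

ΔFRS, the historical progression proxy, is (48 − baseline score) / months
from onset to baseline.  It is stored positive (a decline rate) and negated
wherever it serves as a prediction of a signed slope, so that its scale is
comparable to the outcome.

Trial follow-up splits at a configurable lead-in boundary (default
3 months).  A visit exactly at the boundary belongs to both periods: it
ends the lead-in and is the interventional period's first point.  This
mirrors how a month-3 assessment functions in a lead-in trial and maximizes
the number of patients with ≥ 2 interventional time points.  Interventional
times are re-centered to 0.  `split_periods` subtracts the boundary
globally; the mixed-model design additionally re-centers per patient at the
first retained visit so that t = 0 exists for every patient even when a
patient misses the boundary visit.  On regular visit schedules the two
centerings coincide.

## The prediction model

The shipped published coefficients are

    slope = 4.45 − 1.13 ln(NfL) − 3.82 S + 0.83 S ln(NfL),   S = 1 spinal / 0 bulbar.

NfL enters as its natural log everywhere.  Derived quantities follow in
closed form: the sensitivity (ln-units of NfL per pt/month of predicted
slope change) is the reciprocal of the effective ln(NfL) coefficient
(−1.13 + 0.83 for spinal, −1.13 for bulbar), and the site crossover is
exp(3.82/0.83) ≈ 99.7 pg/ml.

Model development (`NflSlopeRegressor`) starts from eight candidate main
effects — ln(NfL), onset site, sex, age, BMI, disease duration, ΔFRS
(signed), baseline score — plus the single ln(NfL) × site interaction, and
removes the non-significant term with the largest two-sided coefficient
p-value one at a time until all remaining terms have p < α (default 0.05).
The intercept is never removed.  Hierarchy is enforced both ways: an
interaction is only included alongside both parents, and a parent of a
retained interaction is protected from removal.  p-values are standard OLS
t-tests without multiple-testing correction.  Alongside the elimination, an
all-subsets comparison ranks every hierarchy-valid candidate subset by
adjusted R² (ties to fewer terms) with a partial F-test against the
intercept-only model; it serves as a cross-check that subsets containing
ln(NfL) dominate their NfL-free counterparts.  Goodness of fit is reported
as adjusted R² and its square root R.  Patients with missing candidate
values are dropped and listed, never imputed.

## Validation metrics

With y the observed interventional slopes, p the predictions, m = mean(y):

- RMSE = sqrt(mean((y − p)²)),
- CoefD = 1 − Σ(y − p)²/Σ(y − m)² (≤ 1; 0 matches predicting the mean),
- variance change = (var(y − p) − var(y))/var(y) (≥ −1; negative means the
  predictions explain heterogeneity),
- the fraction of patients within ±0.5 pt/month of the observed slope.

Sample variances use the n − 1 denominator; the identity
CoefD = 1 − n·RMSE²/Σ(y − m)² is exercised as a property test.  Each
prediction method (NfL model from baseline NfL + site; negated ΔFRS;
lead-in slope) reports its own n: a patient lacking a valid lead-in slope
drops from the lead-in comparison only.

## Mixed-effects power analysis

The virtual-trial model on interventional rows is

    a_ij = a_i1 + β0 + b_i t_ij + β1 t_ij + β2 t_ij treatment_i + β3 p_i + β4 p_i t_ij

with a single per-patient Gaussian random slope b_i (no random intercept)
and Gaussian residuals, fitted by REML via statsmodels MixedLM.  The fixed
unit-coefficient offset a_i1 (the score at the patient's first
interventional time point) is absorbed by modelling a_ij − a_i1, which is
algebraically identical.  The null model drops β3 and β4.  The saving
statistic is 100·(1 − (SE_alt/SE_null)²) on each model's own SE(β2); no
likelihood-ratio comparison is used.  Constant predictions make the p
columns degenerate; they are dropped with a warning and the saving is 0.

Because the cohorts analysed are placebo arms, treatment labels carry no
information; each permutation draws an equal split (odd n: the larger arm's
side is uniform), refits both models, and records the saving.  The 2.5/97.5%
quantiles over permutations are the Monte-Carlo 95% CI; both mean and median
are reported, with the median as the headline.  Permutations where either
model fails to converge are dropped and counted; the fitter falls back once
from the gradient-based optimizer to derivative-free Powell (the gradient
path can hit a singular score matrix when the random-slope variance
estimate reaches the zero boundary, which happens under near-oracle
predictions), but never restarts from jittered values.  The permutation RNG
is counter-based (numpy Philox) keyed by the seed, so the savings list is
bit-for-bit reproducible.

`permutation_power(..., shuffle_predictions=True)` additionally re-permutes
the prediction-to-patient mapping in every draw.  This is the
uninformative-predictor null: it preserves the predictions' marginal
distribution while destroying their information, and its savings
distribution covers zero.  A single fixed shuffled prediction vector would
not show this — adding two uninformative fixed-effect terms inflates SE(β2)
by a deterministic ~1–2% (an overfitting penalty), so the CI across
treatment assignments alone sits slightly below zero.

## ln(NfL) stability

Per patient: mean over measurements of |ln(NfL)_j − mean_i|/mean_i × 100,
with mean_i the patient's mean ln(NfL); patients need ≥ 2 positive
measurements.  Cohort aggregation is per-measurement → per-patient mean →
across-patient mean and SD, in that fixed order.  The first-follow-up band
is the 2.5/97.5 empirical percentile (linear interpolation between order
statistics) of the signed difference ln(NfL)_followup1 − ln(NfL)_baseline;
the difference is deliberately signed, since a magnitude cannot produce a
negative band edge.

## Synthetic cohorts

`generate_cohort` emulates an ALS cohort at diagnosis.  Per patient:

- onset site ~ Bernoulli(0.78 spinal); ln(NfL)₀ ~ Normal(4.63, 0.81) ln pg/ml;
- true slope = published-model prediction + Normal(0, 0.45) pt/month;
- baseline score ~ round(Normal(42, 2)) clipped to [0, 48]; disease
  duration ~ log-normal with median 10.1 months (σ_ln = 0.8; the IQR is not
  force-matched);
- sex ~ Bernoulli(0.59 male), age ~ Normal(60.1, 11.3) years,
  BMI ~ Normal(25.4, 2.5) kg/m²;
- visits every 3 months to 18 months; observed score =
  round(clip(baseline + slope·t + Normal(0, 1.5), 0, 48));
- visit-level ln(NfL) = ln(NfL)₀·(1 + Normal(0, 0.03)), i.e. ~3% relative
  fluctuation of the ln level, sized to land in the 2.5–4.8% mean
  relative-deviation range typical of repeated blood NfL; the baseline
  record carries the t = 0 measurement.

The per-visit score noise of 1.5 points reflects short-term test–retest
variability of the sum score.  The residual slope SD of 0.45 pt/month is
the heterogeneity the baseline model cannot explain; with the configured
NfL spread it yields an internal-validation R ≈ 0.7 for the refit model.
All draws flow from one seeded generator in a fixed order, so cohorts are
bit-for-bit reproducible.  A truth table of per-patient true slopes is
returned alongside for oracle-based testing.  `generate_trial` additionally
randomizes 1:1 and shifts treated patients' true slopes by the configured
effect.  `simulate_power_design` simulates directly from the mixed-effects
model (known β, variance components) for parameter-recovery checks of the
fitting machinery.

Rounding and clipping are realistic but not innocuous: trajectories of
extreme progressors (floor at 0) and improvers (ceiling at 48) flatten, so
coefficient-recovery checks against the generating formula use the truth
slopes rather than slopes re-estimated from integer trajectories.
`integer_scores=False` disables rounding/clipping for exact-identifiability
diagnostics.

### What the generator does not emulate

- Trajectories are exactly linear.  Real ALSFRS-R courses curve and jitter,
  which makes short-window (lead-in) slopes far noisier in practice than in
  simulation; under the generator, a lead-in slope is a moderately
  informative predictor, so simulated comparisons understate the real-world
  advantage of baseline-biomarker prediction over lead-in observation.
- No dropout, death-informed missingness, or visit-schedule irregularity.
- Covariates other than NfL and site are independent of the true slope, so
  ΔFRS is uninformative by construction in synthetic data (in real cohorts
  it correlates with progression).

Passing tests on synthetic data therefore demonstrate correctness of the
estimation and power machinery under the stated model, not clinical
performance on real cohorts.

## Numerical and design choices

- OLS via numpy least squares; mixed models via statsmodels MixedLM (REML).
- The RMSE is the conventional root of the mean squared error.
- Quantiles: numpy's default linear interpolation.
- Degenerate inputs raise typed errors (insufficient data, undefined
  metric, domain) naming the patient or quantity; cohort validation never
  raises — it reports.
- Times are months everywhere; fractional months allowed.
- All-subsets ranking and backward elimination are both exposed; the
  elimination result is authoritative, the ranking diagnostic.
- Workflow child seeds derive from the top-level seed by hashing the stage
  labels (SHA-256, reduced below 2³¹), so adding a cohort or method does not
  shift the others' draws.
- Problem sizes in the test suite (cohorts of 33–200 patients, 40–500
  permutations, 50–100 replicates) are chosen to give the asserted
  properties comfortable statistical margins while keeping the default
  suite fast on one CPU.

## Known limitations

- The published-coefficient constants are printed to 2–3 significant
  figures; worked-example agreement is asserted at 2 decimals.
- Backward elimination retains a noise covariate with probability ≈ α each,
  so the exact true term set is recovered in a majority — not all — of
  simulated cohorts; coefficient coverage is the stronger guarantee.
- The saving statistic compares SEs between nested fixed-effect structures
  on the same data; it is an in-sample power proxy, not a prospective
  sample-size calculation.
- Analyses of the original study cohorts require their per-patient
  supplementary data files, which are not redistributable here; the
  pipeline ingests them via the column-map CSV reader when available.
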