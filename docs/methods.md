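# Methods

This note records the models, defaults and numerical choices behind
`dietmort`, and what the synthetic data do and do not establish.

## Score computation

All ten indices operate on a per-subject table of food-group intakes
(g/day), nutrient intakes and total energy (kcal/day). Percent-of-energy
conversions use 9 kcal/g fat, 4 kcal/g protein and carbohydrate, and
7 kcal/g ethanol.

**Population-dependent cut-offs.** MDS, rMED, HNFI and DASH rank intakes
within sex; HLI within study center. Two conventions are fixed so that all
oracles are reproducible: quantiles use the linear-interpolation sample
definition (`numpy.quantile` default), and a value exactly at a boundary
falls in the *higher* category ("at or above the median" scores the point).
A component that is constant within a stratum therefore puts every subject
in its top bin, with a `DegenerateCutoffWarning`. Quartile assignment for
the outcome analyses uses the same machinery but sends a fully tied stratum
to the reference quartile 1 instead, so that degenerate strata cannot
inflate the exposed categories.

**Modified scores.** Sodium intake is not part of the data contract, so the
HEI-2010, DQI-I and DASH scores are computed without their sodium
components; the attainable ranges become 0–90, 0–94 and 7–35. All component
standards, serving-size conversions, target windows and step tables live in
`defaults/scores.yaml`; the shipped values follow the original publications
of each index, with two documented simplifications: DQI-I adequacy is
scored as 5·min(1, intake/target) rather than the original energy-dependent
three-tier tables, and the MSDPS olive-oil component follows the same
proration rule as the other twelve components (the original scores it by
exclusivity of use, which intake tables cannot express).

**Choices where the indices are under-specified.** rMED's ninth component
is alcohol, scored 0/2 within a sex-specific moderate window (10–50 g/day
men, 5–25 g/day women); HNFI's sixth component defaults to whole-grain
breakfast cereals; the MDS fat component uses the sex-specific median of the
MUFA/SFA ratio; the HLI health index grades smoking (4/2/0), alcohol
(4 for abstainers, then 3/2/1/0 at 6/12/24 g/day), physical activity
(4/3/1/0), and BMI (4/3/2/1/0 below 22/24/26/30) on 0–4 scales, and the
diet sub-score enters via center-specific quintiles scored 0–4. MSDPS
deducts linearly for over-consumption (component = 10 − 10·(r − 1) for
intake at r > 1 times the recommendation, negatives allowed) and the total
is (Σ components / 130) · 100 · (fraction of energy from pyramid foods).
WCRF sub-components within the weight-gain recommendation (energy density
≤ 125 kcal/100 g solid food; sugary drinks 0 g/day) are averaged.

## Synthetic cohort

The generator emulates the structure of a pan-European prospective cohort:
10 countries with 23 centers, 71.1% women, age ~ truncated normal(50.8,
9.8²) on [25, 70], BMI, smoking, education and physical-activity categories
drawn with sex-specific frequencies matching the published cohort table.

**Intakes.** A latent diet-quality factor z ~ N(0,1) partly drives 17
food-group aggregates whose log intakes are jointly normal; the configured
correlation matrix is the *total* within-sex log-scale correlation (factor
loadings are folded in; the residual Cholesky factor is solved at config
time, and a non-positive-definite configuration is rejected). Sub-groups
(whole vs refined grains, fatty vs white fish, low- vs high-fat dairy, …)
are Dirichlet shares of their aggregate, tilted toward the healthy option
for high-z subjects. Nutrients are composition-matrix transforms of foods
(per-100 g values in `defaults/cohort.yaml`) with 8% multiplicative
log-normal noise; total fat is 1.05·(SFA+MUFA+PUFA); energy equals
macronutrient energy times a noise factor clipped to ±10%. Per-sex scale
factors on all food-group means calibrate expected energy to 2427.9 (men)
and 1935.4 (women) kcal/day; because this shifts both sexes' log-means, the
configured intake correlations hold *within* sex.

**Survival.** Three competing causes (CVD, cancer, other) have Weibull
cause-specific hazards H_c(t) = k_c·t^{a_c}·exp(η_c) with
η_c = β_c·z + age, sex, smoking, activity and BMI effects plus a N(0,
0.15²) per-center offset; the observed event is the earliest latent time
(standard latent-failure construction; cause-specific analyses censor
competing deaths, which this supports). Defaults: β per SD of z = log 0.83
(CVD), log 0.88 (cancer), log 0.85 (other). The baseline scales k_c are
calibrated by root-finding so that the 10-year event fractions match the
configured targets (0.8% CVD, 1.7% cancer, 0.9% other; 3.4% overall) —
first each cause marginally, then a common factor for the all-cause total.
Calibration uses an internal fixed-size reference sample of linear
predictors (default 400,000) drawn from a dedicated child seed, which makes
the scales independent of the cohort size. Administrative censoring is a
per-center horizon cycling through 11–15 years (median follow-up ≈ 13
years), always beyond the 10-year analysis horizon.

**Reproducibility.** All randomness derives from named blocks spawned from
one master seed, each drawing a single subject-major array; the first m
subjects of any cohort are therefore identical for every n ≥ m, and equal
seeds give bit-identical tables.

**What the generator does not emulate:** questionnaire measurement error
and dietary calibration sub-studies, calendar-time recruitment, true
center-level dietary cultures (centers differ only in baseline hazard and
censoring horizon), within-subject reporting correlations beyond the single
latent factor, and missing data. Passing tests therefore demonstrate the
correctness of the *machinery* — scoring arithmetic, stratified estimation,
discrimination/calibration algebra — not the field validity of the scores.

## Statistical analyses

Follow-up is truncated at 10 years (later events censored at 10). Subjects
with prevalent cancer, myocardial infarction, angina, stroke or diabetes
are excluded, with per-reason counts logged. Cause-specific outcomes treat
competing deaths as censored at the death time.

Cox models use follow-up time as the time metric and stratify the baseline
hazard by sex and study center; the optimisation is delegated to
`lifelines.CoxPHFitter` (Efron tie handling — ties are common after
truncation to yearly scales). Model 1 adjusts for age; Model 2 adds BMI
(continuous), smoking (3 categories), physical activity (4), education (4);
the HLI-total model adjusts for education only and the WCRF model for
education and smoking, because those indices already contain the other
covariates; an energy-adjusted variant appends total energy. The quartile
trend test enters the quartile index 1–4 as a single continuous term (Wald
test). Missing covariates are removed listwise with logging.

Harrell's C counts a pair as usable when the earlier time carries an event
(a censored subject tied in time with an event counts as surviving longer;
two events at the same time are not orderable), scores tied predictions
0.5, and reports both the raw value and the max(C, 1−C) convention. The SE
is an exact leave-one-subject-out jackknife computed from per-subject pair
aggregates. Ten-year risks use the per-stratum Breslow baseline cumulative
hazard with the fit's uncentered linear predictor. Calibration deciles are
quantile bins of predicted risk (mass ties merge bins with a warning);
observed risk is 1 − Kaplan–Meier(10 y) within the bin (raw event fraction
by flag); the calibration slope is the Cox coefficient of the linear
predictor refit as sole covariate on the evaluation data. Reported
performance is apparent (in-sample), as is conventional for this design;
the pipeline does not bootstrap an optimism correction.

Country pooling uses DerSimonian–Laird: with fixed-effect weights
w_i = 1/SE_i², Q = Σw_i(θ_i − θ̂_FE)², τ² = max(0, (Q − (k−1))/(Σw −
Σw²/Σw)), I² = max(0, (Q − df)/Q)·100, and random-effects weights
1/(SE_i² + τ²). Log hazard ratios pool on the log scale; C statistics pool
on their own scale with jackknife SEs. Countries with zero events or
non-converging fits are excluded with a log entry.

## Numerical and testing notes

* Problem sizes: unit tests use cohorts of ≤ 8,000 subjects with a reduced
  internal calibration-reference size (the tested quantities do not depend
  on it); the hazard-ratio recovery checks use 50 replicates at n = 100,000
  and 200 replicates at n = 20,000; the self-calibration check uses one
  n = 200,000 cohort. Generator event-fraction calibration is verified with
  a 3σ band on the combined cohort-plus-reference Monte-Carlo error.
* Ratios with zero denominators (MUFA/SFA etc.) map to +∞ (0/0 → 0), so
  fat-free diets rank above any finite ratio under "at or above" rules.
* Degenerate inputs: empty cohorts produce empty score tables; a
  zero-variance stratum is an error for standardization and a warning plus
  single-bin assignment for scoring cut-offs.
* τ² is truncated at zero (classical moment estimator); an unclipped
  estimate (as some libraries report) can be negative and is not used.

## Known limitations

Breslow tie handling is not offered (the lifelines backend implements Efron
only). The aHEI is intentionally absent (it requires sodium and trans-fat
data outside the intake contract). The obesity-related-cancer outcome is a
Bernoulli flag on cancer deaths, not an ICD site list. Optimism-corrected
(cross-validated) performance is available via evaluating a fit on a
held-out cohort with `predict_10y_risk(fit, data, train=...)` but is not
part of the default pipeline.
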