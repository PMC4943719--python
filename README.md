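# dietmort

**A-priori diet-quality scores and 10-year mortality prediction in
multi-center cohorts.**

Nutritional epidemiology summarises a person's diet with *a-priori quality
scores* — indices that award points for adherence to a dietary pattern
(Mediterranean diet, DASH, WHO guidelines, …) using predefined components
and cut-offs. `dietmort` implements ten such scores exactly as they are used
in large European cohort analyses, evaluates their association with
all-cause, cardiovascular and cancer mortality, and measures how well they
*predict* 10-year mortality risk. Because individual-level cohort data of
this kind are not publicly available, the package ships a synthetic
multi-center cohort generator with known ground truth, so every stage of the
analysis is testable end to end.

## What it computes

**Scores** (sodium-free modified versions where the original requires sodium
data): MDS (0–9), rMED (0–18), MSDPS (≤100, negatives possible), DQI-I
(0–94), HNFI (0–6), HEI-2010 (0–90), WHO HDI (0–7), DASH (7–35), HLI (diet
0–63, total 0–20) and the WCRF/AICR score (0–7 women / 0–6 men). Scores with
population-dependent cut-offs derive them from the cohort at hand
(sex-specific medians/tertiles/quintiles, center-specific deciles), with the
tie rule "at or above a boundary counts as the higher category" and
linear-interpolation sample quantiles.

**Survival analysis.** Within sex×center strata, each score is standardized
(z) and ranked into quartiles. Cox proportional-hazards models stratified by
sex and center estimate the hazard ratio per SD of score and by quartile
(Q1 reference, linear-trend Wald test): Model 1 adjusts for age; Model 2
adds BMI, smoking, physical activity and education (reduced sets for the
two scores that already contain lifestyle components).

**Prediction.** Harrell's C over usable pairs (with leave-one-out jackknife
SE), C-improvement over an age-only baseline, 10-year risks from the
per-stratum Breslow baseline hazard, risk = 1 − exp(−H₀(10)·e^lp), decile
calibration tables against Kaplan–Meier observed risk, overall
predicted-to-observed ratio and calibration slope.

**Country pooling.** Country-specific fits combined by DerSimonian–Laird
random-effects meta-analysis with Cochran's Q and
I² = max(0, (Q − df)/Q)·100.

## Worked example

```python
import dietmort as dm
from dietmort.pipeline import run_pipeline

bundle = run_pipeline(n_subjects=8000, seed=4,
                      scores=["mds", "dqi_i", "wcrf", "hli"],
                      outcomes=["all_cause"], meta_analysis=True,
                      out_dir="example_run")
print(bundle["hr_table"][["score", "model", "hr_per_sd", "lcl", "ucl"]])
```

With the default generator (latent diet-quality factor with protective
per-SD log hazard ratios near log 0.85, 10-year all-cause event fraction
calibrated to 3.4%), this prints, e.g.:

```
       score  model  hr_per_sd    lcl    ucl
0        mds      1      0.878  0.770  1.002
1        mds      2      0.882  0.773  1.005
2      dqi_i      1      0.885  0.775  1.010
...
9  hli_total      2      0.728  0.638  0.829
```

i.e. a one-SD higher diet-quality score is associated with a ~12% lower
all-cause mortality hazard, strongest for the combined diet+lifestyle index
— the scores recover (attenuated, because each score is a noisy readout of
the latent factor) the protective effect that generated the data. The run
directory also receives the discrimination table (baseline age-only model
C ≈ 0.71; Model 2 C ≈ 0.73), decile calibration tables/plots (slope ≈ 1.00,
predicted-to-observed ratio ≈ 0.99) and country-level pooled estimates
with I².

The same analyses are available from the shell:

```bash
dietmort simulate --n 10000 --seed 1 --out cohort.csv
dietmort score --cohort cohort.csv --out scores.csv
dietmort run-all --n 10000 --seed 1 --scores mds,dash --out run1
```

## Layout

- `src/dietmort/cohort.py` — synthetic cohort generator (intakes, nutrients,
  Weibull competing-cause survival, per-center censoring)
- `src/dietmort/scores/` — the ten scorers; `cutoffs.py` — quantile machinery
- `src/dietmort/prep.py` — exclusions, 10-year truncation, standardization,
  quartiles
- `src/dietmort/survival.py` — stratified Cox models (lifelines backend)
- `src/dietmort/evaluate.py` — Harrell's C, Breslow risks, calibration
- `src/dietmort/meta.py` — DerSimonian–Laird pooling
- `src/dietmort/defaults/*.yaml` — every threshold, serving conversion and
  generator parameter (editable configuration, never hard-coded)
- `docs/methods.md` — modelling assumptions, defaults and limitations
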