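"""Synthetic-cohort generator: determinism, calibration and intake model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietmort import generate_cohort, inject_prevalent_disease
from dietmort.cohort import ENERGY_FACTORS, generate_intakes
from dietmort.config import load_cohort_config
from dietmort.errors import ConfigError

from conftest import FAST


def test_same_seed_identical_and_prefix_stable():
    """Fixed seed reproduces the table bit for bit, and a shorter cohort is a
    prefix of a longer one (per-subject RNG streams)."""
    a = generate_cohort(n_subjects=500, seed=3, **FAST)
    b = generate_cohort(n_subjects=500, seed=3, **FAST)
    pd.testing.assert_frame_equal(a, b)
    longer = generate_cohort(n_subjects=900, seed=3, **FAST)
    pd.testing.assert_frame_equal(a, longer.iloc[:500].reset_index(drop=True))


def test_basic_invariants(small_cohort):
    df = small_cohort
    food_cols = [c for c in df.columns if c.startswith("foodgroup_")]
    assert (df[food_cols] > 0).all().all()
    assert (df["time_y"] > 0).all()
    assert (df.loc[df.event == 0, "cause"] == "none").all()
    assert df["age"].between(25, 70).all()
    assert (df["bmi"] > 0).all()
    # subgroup intakes never exceed their aggregate
    agg = {"fruit": ["apples_pears", "other_fruit"],
           "vegetables": ["cabbage", "root_vegetables", "other_vegetables"],
           "dairy": ["high_fat_dairy", "low_fat_dairy"]}
    for parent, parts in agg.items():
        total = sum(df[f"foodgroup_{p}_g"] for p in parts)
        np.testing.assert_allclose(total, df[f"foodgroup_{parent}_g"], rtol=1e-9)


def test_energy_consistent_with_macronutrients(small_cohort):
    df = small_cohort
    macro = (ENERGY_FACTORS["fat"] * df.nutrient_fat_g
             + ENERGY_FACTORS["protein"] * df.nutrient_protein_g
             + ENERGY_FACTORS["carbohydrate"] * df.nutrient_carb_g
             + ENERGY_FACTORS["ethanol"] * df.nutrient_ethanol_g)
    assert (np.abs(df.energy_kcal / macro - 1.0) <= 0.10 + 1e-12).all()


def test_fruit_vegetable_log_correlation_matches_config():
    """The configured total correlation of 0.3 between fruit and vegetables
    is recovered by the sample log-intake correlation within +-0.02.  The
    intake model is sex-conditional (a sex-specific energy scale shifts all
    log-means), so the correlation is measured within one sex."""
    df = generate_cohort(n_subjects=50000, seed=21, **FAST)
    for sex in ("male", "female"):
        sub = df[df.sex == sex]
        r = np.corrcoef(np.log(sub.foodgroup_fruit_g),
                        np.log(sub.foodgroup_vegetables_g))[0, 1]
        assert abs(r - 0.3) < 0.02, sex


def test_degenerate_zero_scale_gives_identical_intakes():
    defaults = load_cohort_config()["intake_model"]["food_groups"]
    overrides = {"intake_model": {"food_groups": {
        g: {"mean": spec["mean"], "sdlog": 0.0, "loading": 0.0}
        for g, spec in defaults.items()}}}
    df = generate_cohort(n_subjects=50, seed=5, **FAST, **overrides)
    male = df[df.sex == "male"]
    assert male.foodgroup_fruit_g.nunique() == 1
    assert male.foodgroup_meat_g.nunique() == 1


def test_identity_composition_single_food_toy(rng):
    """With a one-food intake model and an identity-like composition row the
    nutrient equals the food intake up to the multiplicative noise term."""
    cfg = load_cohort_config()
    cfg["intake_model"]["food_groups"] = {
        "fruit": {"mean": 100.0, "sdlog": 0.3, "loading": 0.0}}
    cfg["intake_model"]["correlations"] = []
    cfg["intake_model"]["subgroups"] = {}
    cfg["intake_model"]["composition"] = {
        "sfa_g": {"fruit": 1.0}, "mufa_g": {"fruit": 1.0},
        "pufa_g": {"fruit": 1.0}, "protein_g": {"fruit": 10.0},
        "carb_g": {"fruit": 10.0}, "ethanol_g": {},
        "tracer_g": {"fruit": 100.0},
    }
    z = np.zeros(2000)
    female = np.zeros(2000, dtype=bool)
    rngs = [np.random.default_rng(s) for s in range(4)]
    out = generate_intakes(cfg, z, female, *rngs)
    ratio = out["nutrient_tracer_g"] / out["foodgroup_fruit_g"]
    sd = cfg["intake_model"]["nutrient_noise_sdlog"]
    assert np.abs(np.log(ratio)).max() < 6 * sd
    assert abs(np.log(ratio).std() - sd) < 0.02


def test_non_positive_definite_correlation_is_config_error():
    overrides = {"intake_model": {"correlations": [
        ["fruit", "vegetables", 0.99], ["fruit", "legumes", 0.99],
        ["vegetables", "legumes", -0.99]]}}
    with pytest.raises(ConfigError, match="positive definite"):
        generate_cohort(n_subjects=10, seed=0, **FAST, **overrides)


def test_ten_year_event_fraction_calibrated_to_default_target():
    """With default parameters the 10-year all-cause event fraction matches
    the configured 3.4% target within combined Monte-Carlo error."""
    df = generate_cohort(n_subjects=200000, seed=31, simulate_diet=False)
    frac = ((df.event == 1) & (df.time_y <= 10.0)).mean()
    se = np.sqrt(0.034 * 0.966 * (1 / 200000 + 1 / 400000))
    assert abs(frac - 0.034) < 3 * se


def test_event_fraction_monotone_in_baseline_scale():
    """Raising a cause's 10-year target raises its observed event share."""
    lo = generate_cohort(n_subjects=30000, seed=7, simulate_diet=False, **FAST)
    hi = generate_cohort(n_subjects=30000, seed=7, simulate_diet=False,
                         hazards={"calibration_n": 20000,
                                  "ten_year_fraction": {"cvd": 0.024}})
    assert (hi.cause == "cvd").mean() > (lo.cause == "cvd").mean() * 1.5


def test_survivor_function_matches_weibull_closed_form():
    """With all covariate and latent effects switched off, Kaplan-Meier of the
    generated times equals the calibrated Weibull survivor function."""
    from lifelines import KaplanMeierFitter

    zero = {c: 0.0 for c in ("cvd", "cancer", "other")}
    df = generate_cohort(
        n_subjects=40000, seed=13, simulate_diet=False,
        countries={"Spain": 1},
        hazards={"calibration_n": 20000, "true_loghr_per_sd": zero,
                 "age_loghr": zero, "male_loghr": zero,
                 "smoking_loghr": {"former": zero, "current": zero},
                 "pa_loghr_per_level": zero, "bmi_loghr_per_unit": zero,
                 "center_log_offset_sd": 0.0})
    cfg = load_cohort_config()
    shapes = {c: cfg["hazards"]["weibull_shape"][c] for c in zero}
    targets = {c: cfg["hazards"]["ten_year_fraction"][c] for c in zero}
    # closed-form calibration with degenerate linear predictors
    k = {c: -np.log1p(-targets[c]) / 10.0 ** shapes[c] for c in zero}
    total10 = sum(k[c] * 10.0 ** shapes[c] for c in zero)
    alpha = -np.log1p(-sum(targets.values())) / total10
    km = KaplanMeierFitter().fit(df.time_y, df.event)
    for t in (2.0, 5.0, 10.0):
        s_true = np.exp(-alpha * sum(k[c] * t ** shapes[c] for c in zero))
        mc = 3 * np.sqrt((1 - s_true) * s_true / 40000) + 0.002
        assert abs(float(km.predict(t)) - s_true) < mc


@pytest.mark.parametrize("rate,expect", [(0.0, 0), (1.0, 100)])
def test_prevalent_flags_degenerate_rates(rate, expect):
    table = pd.DataFrame({"subject_id": range(100)})
    out = inject_prevalent_disease(table, {"diabetes": rate}, seed=1)
    assert out["prev_diabetes"].sum() == expect


def test_prevalent_flag_rate_within_binomial_interval():
    table = pd.DataFrame({"subject_id": range(100000)})
    out = inject_prevalent_disease(table, {"cancer": 0.05}, seed=2)
    lo, hi = stats.binom.interval(0.99, 100000, 0.05)
    assert lo <= out["prev_cancer"].sum() <= hi


def test_invalid_rate_raises_config_error():
    with pytest.raises(ConfigError, match="prevalence_rates.diabetes"):
        inject_prevalent_disease(pd.DataFrame({"a": [1]}), {"diabetes": 1.5})
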