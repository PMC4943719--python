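"""Reference diet profiles: synthetic single subjects or tiny cohorts built
to sit at known points of each score's range (best/worst levels, exact
adherence to recommendations).  They document what each score rewards and
give closed-form expected values for verification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import load_score_config

ALL_FOODGROUPS = [
    "fruit", "apples_pears", "other_fruit", "vegetables", "cabbage",
    "root_vegetables", "other_vegetables", "legumes", "nuts", "total_grains",
    "whole_grain_bread", "whole_grain_cereals", "refined_grains",
    "fish_shellfish", "white_fish", "fatty_fish", "meat",
    "red_processed_meat", "poultry", "dairy", "high_fat_dairy",
    "low_fat_dairy", "eggs", "potatoes", "sweets", "sugary_drinks",
    "olive_oil", "olives", "margarine", "wine", "other_alcohol",
]

ALL_NUTRIENTS = [
    "sfa_g", "mufa_g", "pufa_g", "fat_g", "protein_g", "carb_g",
    "free_sugars_g", "cholesterol_mg", "fibre_g", "cereal_fibre_g",
    "folate_ug", "iron_mg", "calcium_mg", "vitamin_c_mg", "ethanol_g",
    "glycaemic_load",
]

LIFESTYLE_DEFAULTS = {
    "sex": "female", "age": 50.0, "bmi": 22.0, "smoking": "never",
    "education": "longer", "pa_cambridge": "active", "breastfed": True,
}


def blank_profile(n: int = 1, energy_kcal: float = 2000.0, **overrides
                  ) -> pd.DataFrame:
    """A cohort of ``n`` subjects with zero intakes and default lifestyle."""
    data = {"subject_id": np.arange(n)}
    for k, v in LIFESTYLE_DEFAULTS.items():
        data[k] = [overrides.pop(k, v)] * n
    for g in ALL_FOODGROUPS:
        data[f"foodgroup_{g}_g"] = 0.0
    for nu in ALL_NUTRIENTS:
        data[f"nutrient_{nu}"] = 0.0
    data["energy_kcal"] = energy_kcal
    df = pd.DataFrame(data)
    for col, val in overrides.items():
        df[col] = val
    return df


def optimal_dqi_profile(config: dict | None = None) -> pd.DataFrame:
    """One subject meeting every DQI-I variety, adequacy, moderation and
    balance criterion at its best level (expected total: the configured
    maximum, 94 points with sodium removed).

    The construction reads the configured targets: adequacy components sit at
    their targets, the macronutrient split is 60:14:18 %E (within the best
    balance window, with 4.5 %E saturated fat), the fatty-acid profile has
    PUFA/SFA = 1.2 and MUFA/SFA = 1.7, and no empty-energy foods are consumed.
    """
    cfg = (load_score_config() if config is None else config)["dqi_i"]
    energy = 2000.0
    df = blank_profile(1, energy_kcal=energy)
    serv = cfg["serving_g"]
    adequacy = cfg["adequacy"]
    fgs = {
        "vegetables": adequacy["vegetable_servings"] * serv["vegetable"],
        "fruit": adequacy["fruit_servings"] * serv["fruit"],
        "total_grains": adequacy["grain_servings"] * serv["grain"],
        "fish_shellfish": 50.0, "eggs": 25.0, "dairy": 200.0,
        "legumes": 40.0, "meat": 30.0,
    }
    for g, v in fgs.items():
        df[f"foodgroup_{g}_g"] = v
    nuts = {
        "carb_g": 0.60 * energy / 4.0,
        "protein_g": 0.14 * energy / 4.0,
        "fat_g": 0.18 * energy / 9.0,
        "sfa_g": 10.0, "mufa_g": 17.0, "pufa_g": 12.0,
        "cholesterol_mg": 100.0,
        "fibre_g": adequacy["fibre_g"], "iron_mg": adequacy["iron_mg"],
        "calcium_mg": adequacy["calcium_mg"],
        "vitamin_c_mg": adequacy["vitamin_c_mg"],
    }
    for nu, v in nuts.items():
        df[f"nutrient_{nu}"] = v
    return df


def dash_extreme_cohort(sex: str = "female") -> pd.DataFrame:
    """A 10-subject single-sex stratum in which subject 9 sits in the most
    favorable quintile of all seven retained DASH components and subject 0 in
    the least favorable (expected scores 35 and 7)."""
    n = 10
    df = blank_profile(n, sex=sex)
    beneficial = np.arange(1, n + 1) * 10.0
    harmful = np.arange(n, 0, -1) * 10.0
    for g in ("fruit", "vegetables", "legumes", "whole_grain_bread",
              "low_fat_dairy"):
        df[f"foodgroup_{g}_g"] = beneficial
    for g in ("sugary_drinks", "red_processed_meat"):
        df[f"foodgroup_{g}_g"] = harmful
    return df


def msdps_reference_profile(config: dict | None = None,
                            fractions: dict[str, float] | None = None
                            ) -> pd.DataFrame:
    """One subject consuming ``fractions`` (default 1.0) of every MSDPS
    component's recommended servings, with all energy supplied by the
    pyramid foods (so the Mediterranean-energy fraction is 1)."""
    cfg = (load_score_config() if config is None else config)["msdps"]
    fractions = fractions or {}
    df = blank_profile(1)
    total_kcal = 0.0
    for name, comp in cfg["components"].items():
        frac = float(fractions.get(name, 1.0))
        grams = frac * comp["recommended_per_day"] * comp["serving_g"]
        first_food = comp["foods"][0]
        df[f"foodgroup_{first_food}_g"] += grams
        total_kcal += grams * comp["kcal_per_g"]
    df["energy_kcal"] = total_kcal
    return df


def who_hdi_reference_profile(config: dict | None = None) -> pd.DataFrame:
    """One subject inside every WHO healthy-diet target range (expected 7)."""
    cfg = (load_score_config() if config is None else config)["who_hdi"]["targets"]
    energy = 2000.0
    df = blank_profile(1, energy_kcal=energy)

    def mid(window, cap=1e9):
        lo, hi = float(window[0]), min(float(window[1]), cap)
        return (lo + hi) / 2.0

    df["nutrient_sfa_g"] = mid(cfg["sfa_pct_e"]) / 100.0 * energy / 9.0
    df["nutrient_pufa_g"] = mid(cfg["pufa_pct_e"]) / 100.0 * energy / 9.0
    df["nutrient_protein_g"] = mid(cfg["protein_pct_e"]) / 100.0 * energy / 4.0
    df["nutrient_cholesterol_mg"] = mid(cfg["cholesterol_mg"])
    df["nutrient_fibre_g"] = mid(cfg["fibre_g"])
    df["nutrient_free_sugars_g"] = mid(cfg["free_sugars_pct_e"]) / 100.0 * energy / 4.0
    half = mid(cfg["fruit_veg_g"], cap=2.0 * float(cfg["fruit_veg_g"][0])) / 2.0
    df["foodgroup_fruit_g"] = half
    df["foodgroup_vegetables_g"] = half
    return df
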