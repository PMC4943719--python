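"""Scores combining diet with lifestyle: HLI and the WCRF/AICR guideline score.

**HLI**: the healthy-diet sub-score ranks seven diet components into
center-specific deciles scored 0-9 (reversed for margarine, a trans-fat
marker, and glycaemic load), summing to 0-63.  The total index adds 0-4
points each for smoking, alcohol, physical activity, BMI and the
center-specific quintile of the diet sub-score (0-20 in total).  The 0-4
gradings for the lifestyle components are a documented default mapping.

**WCRF/AICR**: each recommendation is scored 1 / 0.5 / 0 against configured
cut-offs; the foods-promoting-weight-gain recommendation averages its energy
density and sugary-drink sub-components.  Women are additionally scored on
breastfeeding (range 0-7 for women, 0-6 for men).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..cutoffs import CutoffSet, derive_cutoffs
from .base import (as_components, energy, fg, fruit_veg, lifestyle, nut,
                   require_sex, safe_ratio, score_config)

HLI_DIET_COMPONENTS = ["cereal_fibre", "folate", "pufa_sfa_ratio", "fatty_fish",
                       "margarine", "glycaemic_load", "fruit_veg"]

#: solid foods used in the WCRF energy-density denominator (aggregates only)
SOLID_FOODS = ["fruit", "vegetables", "legumes", "nuts", "total_grains",
               "fish_shellfish", "meat", "dairy", "eggs", "potatoes",
               "sweets", "olive_oil", "olives", "margarine"]


def _hli_diet_values(df: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        "cereal_fibre": nut(df, "cereal_fibre_g"),
        "folate": nut(df, "folate_ug"),
        "pufa_sfa_ratio": safe_ratio(nut(df, "pufa_g"), nut(df, "sfa_g")),
        "fatty_fish": fg(df, "fatty_fish"),
        "margarine": fg(df, "margarine"),
        "glycaemic_load": nut(df, "glycaemic_load"),
        "fruit_veg": fruit_veg(df),
    }


def derive_hli_cutoffs(df: pd.DataFrame) -> CutoffSet:
    return derive_cutoffs(df, _hli_diet_values(df), "deciles", strata=("center",))


def _graded(value: pd.Series, bounds: list[float], top: int = 4) -> pd.Series:
    """<bounds[0] -> top, <bounds[1] -> top-1, ..., >= last bound -> lower."""
    conds = [value < float(b) for b in bounds]
    choices = [float(top - i) for i in range(len(bounds))]
    return pd.Series(np.select(conds, choices, float(top - len(bounds))),
                     index=value.index)


def compute_hli(df: pd.DataFrame, cutoffs: CutoffSet | None = None,
                config: dict | None = None, return_components: bool = False):
    """Healthy Lifestyle Index: returns ``(diet_score 0-63, total 0-20)``."""
    cfg = score_config(config)["hli"]
    vals = _hli_diet_values(df)
    if cutoffs is None:
        cutoffs = derive_cutoffs(df, vals, "deciles", strata=("center",))
    parts: dict[str, pd.Series] = {}
    for name in HLI_DIET_COMPONENTS:
        rank = cutoffs.assign(df, name, vals[name])
        parts[f"diet_{name}"] = 9 - rank if name in cfg["reversed_components"] else rank
    diet = sum(parts[f"diet_{c}"] for c in HLI_DIET_COMPONENTS).astype(int)

    smoking = lifestyle(df, "smoking").map(
        {k: float(v) for k, v in cfg["smoking_points"].items()})
    eth = nut(df, "ethanol_g")
    alcohol = _graded(eth, cfg["alcohol_points_bounds"], top=3)
    alcohol = alcohol.where(eth > 0, 4.0)  # full points for abstainers
    pa = lifestyle(df, "pa_cambridge").map(
        {k: float(v) for k, v in cfg["pa_points"].items()})
    bmi = _graded(lifestyle(df, "bmi").astype(float), cfg["bmi_points_bounds"], top=4)
    diet_quintiles = derive_cutoffs(df.assign(_hli_diet=diet),
                                    {"_hli_diet": diet}, "quintiles",
                                    strata=("center",))
    diet_q = diet_quintiles.assign(df, "_hli_diet", diet).astype(float)
    for name, series in (("smoking", smoking), ("alcohol", alcohol), ("pa", pa),
                         ("bmi", bmi), ("diet_quintile", diet_q)):
        if series.isna().any():
            raise ValueError(f"HLI lifestyle component {name!r} has missing values")
        parts[name] = series
    total = (smoking + alcohol + pa + bmi + diet_q).astype(int)
    diet = diet.rename("hli_diet")
    total = total.rename("hli_total")
    if return_components:
        return diet, total, pd.DataFrame(parts, index=df.index)
    return diet, total


def _tiered(value: pd.Series, full_ok: pd.Series, half_ok: pd.Series) -> pd.Series:
    return pd.Series(np.select([full_ok, half_ok], [1.0, 0.5], 0.0),
                     index=value.index)


def compute_wcrf(df: pd.DataFrame, config: dict | None = None,
                 return_components: bool = False):
    """WCRF/AICR cancer-prevention guideline score (0-7 women, 0-6 men)."""
    cfg = score_config(config)["wcrf"]
    sex = require_sex(df)
    female = sex == "female"
    parts: dict[str, pd.Series] = {}

    bmi = lifestyle(df, "bmi").astype(float)
    parts["weight"] = _tiered(
        bmi,
        (bmi >= cfg["bmi_full"][0]) & (bmi < cfg["bmi_full"][1]),
        (bmi >= cfg["bmi_half"][0]) & (bmi < cfg["bmi_half"][1]))

    pa = lifestyle(df, "pa_cambridge")
    parts["physical_activity"] = _tiered(
        pd.Series(0.0, index=df.index),
        pa.isin(cfg["pa_full"]), pa.isin(cfg["pa_half"]))

    solid_g = sum((fg(df, food) for food in SOLID_FOODS),
                  pd.Series(0.0, index=df.index))
    ed = energy(df) / solid_g.where(solid_g > 0, np.nan) * 100.0
    ed = ed.fillna(np.inf)
    ed_pts = _tiered(ed, ed <= cfg["energy_density_full"],
                     ed <= cfg["energy_density_half"])
    drinks = fg(df, "sugary_drinks")
    drink_pts = _tiered(drinks, drinks <= cfg["sugary_drinks_full"],
                        drinks <= cfg["sugary_drinks_half"])
    parts["weight_gain_foods"] = (ed_pts + drink_pts) / 2.0

    fv = fruit_veg(df)
    parts["plant_foods"] = _tiered(fv, fv >= cfg["fruit_veg_full"],
                                   fv >= cfg["fruit_veg_half"])

    rpm = fg(df, "red_processed_meat")
    parts["animal_foods"] = _tiered(rpm, rpm < cfg["red_processed_meat_full"],
                                    rpm < cfg["red_processed_meat_half"])

    eth = nut(df, "ethanol_g")
    full = np.where(female, cfg["ethanol_full"]["female"], cfg["ethanol_full"]["male"])
    half = np.where(female, cfg["ethanol_half"]["female"], cfg["ethanol_half"]["male"])
    parts["alcohol"] = _tiered(eth, eth <= full, eth <= half)

    breastfed = lifestyle(df, "breastfed").astype(bool)
    parts["breastfeeding"] = pd.Series(
        np.where(female, breastfed.astype(float), 0.0), index=df.index)

    total = sum(parts.values())
    return as_components(total.rename("wcrf"), parts, return_components)
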