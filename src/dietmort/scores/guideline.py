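"""Guideline-based scores: WHO Healthy Diet Indicator, HEI-2010 and DQI-I.

All cut-offs, serving conversions and component standards are configuration
(see ``defaults/scores.yaml``); the sodium components of HEI-2010 and DQI-I
are removed in the default configuration, giving modified maxima of 90 and
94 points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..errors import ConfigError
from .base import (as_components, energy, fg, fruit_veg, in_window, nut,
                   pct_energy, safe_ratio, score_config)


# ---------------------------------------------------------------------------
# WHO Healthy Diet Indicator
# ---------------------------------------------------------------------------

def _who_values(df: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        "sfa_pct_e": pct_energy(df, "sfa_g", "fat"),
        "pufa_pct_e": pct_energy(df, "pufa_g", "fat"),
        "protein_pct_e": pct_energy(df, "protein_g", "protein"),
        "cholesterol_mg": nut(df, "cholesterol_mg"),
        "fibre_g": nut(df, "fibre_g"),
        "fruit_veg_g": fruit_veg(df),
        "free_sugars_pct_e": pct_energy(df, "free_sugars_g", "carbohydrate"),
    }


def compute_who_hdi(df: pd.DataFrame, config: dict | None = None,
                    return_components: bool = False):
    """WHO Healthy Diet Indicator, integer 0-7: one point per nutrient or
    food-group component within its predefined target range."""
    cfg = score_config(config)["who_hdi"]
    vals = _who_values(df)
    parts = {name: in_window(vals[name], window).astype(int)
             for name, window in cfg["targets"].items()}
    total = sum(parts.values()).astype(int)
    return as_components(total.rename("who_hdi"), parts, return_components)


# ---------------------------------------------------------------------------
# HEI-2010 (modified: sodium removed)
# ---------------------------------------------------------------------------

def hei2010_max_points(config: dict | None = None) -> float:
    cfg = score_config(config)["hei2010"]
    return sum(c["max_points"] for c in cfg["components"].values()
               if not c.get("removed", False))


def compute_hei2010(df: pd.DataFrame, config: dict | None = None,
                    return_components: bool = False):
    """HEI-2010 with densities per 1000 kcal and linear proration between the
    zero-point and full-point standards; moderation components reverse-scored."""
    cfg = score_config(config)["hei2010"]
    kcal = energy(df)
    per_1000 = kcal / 1000.0
    parts: dict[str, pd.Series] = {}
    for name, comp in cfg["components"].items():
        if comp.get("removed", False):
            continue
        kind = comp["kind"]
        maxp = float(comp["max_points"])
        full, zero = float(comp["full_std"]), float(comp["zero_std"])
        if kind == "ratio":
            value = safe_ratio(nut(df, "mufa_g") + nut(df, "pufa_g"), nut(df, "sfa_g"))
        elif kind == "pct_energy_moderation":
            empty_kcal = sum(fg(df, food) * k for food, k
                             in cfg["empty_calorie_kcal_per_g"].items())
            empty_kcal = empty_kcal + nut(df, "ethanol_g") * 7.0
            value = empty_kcal / kcal * 100.0
        else:
            grams = sum((fg(df, food) for food in comp["foods"]),
                        pd.Series(0.0, index=df.index))
            value = grams / float(comp["g_per_unit"]) / per_1000
        if kind in ("moderation", "pct_energy_moderation"):
            frac = (zero - value) / (zero - full)
        else:
            frac = (value - zero) / (full - zero)
        parts[name] = maxp * np.clip(frac, 0.0, 1.0)
    total = sum(parts.values())
    return as_components(total.rename("hei2010"), parts, return_components)


# ---------------------------------------------------------------------------
# DQI-I (modified: sodium removed)
# ---------------------------------------------------------------------------

def _step_points(value: pd.Series, cuts, points=(6.0, 3.0, 0.0)) -> pd.Series:
    c1, c2 = float(cuts[0]), float(cuts[1])
    return pd.Series(np.select([value <= c1, value <= c2], points[:2], points[2]),
                     index=value.index)


def compute_dqi_i(df: pd.DataFrame, config: dict | None = None,
                  return_components: bool = False):
    """Diet Quality Index-International: variety + adequacy + moderation
    (sodium removed) + overall balance; modified maximum 94 points."""
    cfg = score_config(config)["dqi_i"]
    serv = cfg["serving_g"]
    kcal = energy(df)
    parts: dict[str, pd.Series] = {}

    # --- variety: servings from each of the five major food groups
    group_servings = {
        "protein": (fg(df, "meat") + fg(df, "fish_shellfish") + fg(df, "eggs"))
        / serv["protein"],
        "dairy_bean": (fg(df, "dairy") + fg(df, "legumes")) / serv["dairy_bean"],
        "grain": fg(df, "total_grains") / serv["grain"],
        "fruit": fg(df, "fruit") / serv["fruit"],
        "vegetable": fg(df, "vegetables") / serv["vegetable"],
    }
    n_groups = sum((s >= 1.0).astype(int) for s in group_servings.values())
    overall_map = {int(k): float(v) for k, v in cfg["variety_overall_points"].items()}
    parts["variety_overall"] = n_groups.map(overall_map)

    sources = cfg["protein_source_min_g"]
    counts = sum((fg(df, food) >= float(g)).astype(int) for food, g in sources.items())
    vp = {int(k): float(v) for k, v in cfg["protein_variety_points"].items()}
    thresholds = sorted(vp, reverse=True)
    parts["variety_protein"] = pd.Series(
        np.select([counts >= t for t in thresholds], [vp[t] for t in thresholds], 0.0),
        index=df.index)

    # --- adequacy: 5 * min(1, value / target) each
    adequacy_values = {
        "vegetable_servings": group_servings["vegetable"],
        "fruit_servings": group_servings["fruit"],
        "grain_servings": group_servings["grain"],
        "fibre_g": nut(df, "fibre_g"),
        "protein_pct_e": pct_energy(df, "protein_g", "protein"),
        "iron_mg": nut(df, "iron_mg"),
        "calcium_mg": nut(df, "calcium_mg"),
        "vitamin_c_mg": nut(df, "vitamin_c_mg"),
    }
    for name, target in cfg["adequacy"].items():
        if name not in adequacy_values:
            raise ConfigError(f"dqi_i.adequacy: unknown component {name!r}")
        parts[f"adequacy_{name}"] = 5.0 * np.minimum(
            1.0, adequacy_values[name] / float(target))

    # --- moderation (0/3/6 steps), sodium removed
    empty_kcal = sum(fg(df, food) * k
                     for food, k in cfg["empty_energy_kcal_per_g"].items())
    empty_kcal = empty_kcal + nut(df, "ethanol_g") * 7.0
    moderation_values = {
        "total_fat_pct_e": pct_energy(df, "fat_g", "fat"),
        "sfa_pct_e": pct_energy(df, "sfa_g", "fat"),
        "cholesterol_mg": nut(df, "cholesterol_mg"),
        "empty_energy_pct_e": empty_kcal / kcal * 100.0,
    }
    for name, cuts in cfg["moderation"].items():
        parts[f"moderation_{name}"] = _step_points(moderation_values[name], cuts)

    # --- overall balance
    carb_e = pct_energy(df, "carb_g", "carbohydrate")
    prot_e = pct_energy(df, "protein_g", "protein")
    fat_e = pct_energy(df, "fat_g", "fat")
    macro = pd.Series(0.0, index=df.index)
    for w in cfg["balance"]["macro_windows"]:
        hit = (in_window(carb_e, w["carb"]) & in_window(prot_e, w["protein"])
               & in_window(fat_e, w["fat"]))
        macro = macro.where(~((macro == 0.0) & hit), float(w["points"]))
    parts["balance_macro"] = macro

    ps = safe_ratio(nut(df, "pufa_g"), nut(df, "sfa_g"))
    ms = safe_ratio(nut(df, "mufa_g"), nut(df, "sfa_g"))
    fatty = pd.Series(0.0, index=df.index)
    for w in cfg["balance"]["fatty_acid_windows"]:
        hit = in_window(ps, w["ps"]) & in_window(ms, w["ms"])
        fatty = fatty.where(~((fatty == 0.0) & hit), float(w["points"]))
    parts["balance_fatty_acid"] = fatty

    total = sum(parts.values())
    return as_components(total.rename("dqi_i"), parts, return_components)
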