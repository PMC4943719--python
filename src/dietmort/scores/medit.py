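"""Mediterranean-pattern scores: MDS, rMED and MSDPS.

* **MDS** (0-9): one point per beneficial food group at or above the
  sex-specific median (fruit, vegetables, legumes, grains, fish), one point
  per detrimental group below it (meat, dairy), one point for a MUFA/SFA
  ratio at or above the sex-specific median, and one point for ethanol intake
  within a sex-specific moderate window.
* **rMED** (0-18): the same food groups ranked into sex-specific tertiles
  scored 0/1/2 (reversed for meat and dairy), olive oil scored 0 for
  non-consumption / 1 below the consumers' median / 2 at or above it, and 2
  points for alcohol within the moderate window.
* **MSDPS** (up to 100, negatives possible): thirteen components scored
  10·r for intake at fraction r <= 1 of the recommended servings and
  10 - 10·(r-1) beyond it, summed, rescaled by 100/130 and multiplied by the
  fraction of energy derived from Mediterranean-pyramid foods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..cutoffs import CutoffSet, derive_cutoffs
from ..errors import ConfigError
from .base import (as_components, energy, fg, in_window, nut, require_sex,
                   safe_ratio, score_config)

MDS_BENEFICIAL = ["fruit", "vegetables", "legumes", "total_grains", "fish_shellfish"]
MDS_DETRIMENTAL = ["meat", "dairy"]


def _mds_values(df: pd.DataFrame) -> dict[str, pd.Series]:
    vals = {name: fg(df, name) for name in MDS_BENEFICIAL + MDS_DETRIMENTAL}
    vals["mufa_sfa_ratio"] = safe_ratio(nut(df, "mufa_g"), nut(df, "sfa_g"))
    return vals


def derive_mds_cutoffs(df: pd.DataFrame) -> CutoffSet:
    return derive_cutoffs(df, _mds_values(df), "median", strata=("sex",))


def compute_mds(df: pd.DataFrame, cutoffs: CutoffSet | None = None,
                config: dict | None = None, return_components: bool = False):
    """Mediterranean Diet Score, integer 0-9 per subject."""
    cfg = score_config(config)["mds"]
    sex = require_sex(df)
    vals = _mds_values(df)
    if cutoffs is None:
        cutoffs = derive_cutoffs(df, vals, "median", strata=("sex",))
    parts: dict[str, pd.Series] = {}
    for name in MDS_BENEFICIAL:
        parts[name] = cutoffs.assign(df, name, vals[name])  # bin 1 == at/above median
    for name in MDS_DETRIMENTAL:
        parts[name] = 1 - cutoffs.assign(df, name, vals[name])
    parts["mufa_sfa_ratio"] = cutoffs.assign(df, "mufa_sfa_ratio", vals["mufa_sfa_ratio"])
    eth = nut(df, "ethanol_g")
    windows = cfg["ethanol_window"]
    parts["ethanol"] = pd.Series(
        np.where(sex == "female", in_window(eth, windows["female"]),
                 in_window(eth, windows["male"])).astype(int), index=df.index)
    total = sum(parts.values()).astype(int)
    return as_components(total.rename("mds"), parts, return_components)


RMED_BENEFICIAL = MDS_BENEFICIAL
RMED_DETRIMENTAL = MDS_DETRIMENTAL


def derive_rmed_cutoffs(df: pd.DataFrame) -> dict:
    vals = {name: fg(df, name) for name in RMED_BENEFICIAL + RMED_DETRIMENTAL}
    tertiles = derive_cutoffs(df, vals, "tertiles", strata=("sex",))
    oil = fg(df, "olive_oil")
    consumers = df[oil > 0]
    med = (consumers.assign(_oil=oil[oil > 0]).groupby("sex")["_oil"].median()
           if len(consumers) else pd.Series(dtype=float))
    return {"tertiles": tertiles, "olive_oil_median": med.to_dict()}


def compute_rmed(df: pd.DataFrame, cutoffs: dict | None = None,
                 config: dict | None = None, return_components: bool = False):
    """Relative Mediterranean diet score, integer 0-18 per subject."""
    cfg = score_config(config)["rmed"]
    sex = require_sex(df)
    if cutoffs is None:
        cutoffs = derive_rmed_cutoffs(df)
    tert: CutoffSet = cutoffs["tertiles"]
    parts: dict[str, pd.Series] = {}
    for name in RMED_BENEFICIAL:
        parts[name] = tert.assign(df, name, fg(df, name))
    for name in RMED_DETRIMENTAL:
        parts[name] = 2 - tert.assign(df, name, fg(df, name))
    oil = fg(df, "olive_oil")
    med = sex.map(cutoffs["olive_oil_median"]).astype(float)
    oil_pts = np.where(oil <= 0, 0, np.where(oil >= med, 2, 1))
    parts["olive_oil"] = pd.Series(oil_pts, index=df.index)
    eth = nut(df, "ethanol_g")
    windows = cfg["alcohol_window"]
    ok = np.where(sex == "female", in_window(eth, windows["female"]),
                  in_window(eth, windows["male"]))
    parts["alcohol"] = pd.Series(2 * ok.astype(int), index=df.index)
    total = sum(parts.values()).astype(int)
    return as_components(total.rename("rmed"), parts, return_components)


def msdps_component_score(servings: pd.Series, recommended: float) -> pd.Series:
    """10 points at exact adherence; 10·r below it, 10-10·(r-1) above it."""
    if recommended <= 0:
        raise ConfigError("msdps: recommended_per_day must be positive")
    r = servings / recommended
    return pd.Series(np.where(r <= 1.0, 10.0 * r, 10.0 - 10.0 * (r - 1.0)),
                     index=servings.index)


def compute_msdps(df: pd.DataFrame, config: dict | None = None,
                  return_components: bool = False):
    """Mediterranean Style Dietary Pattern Score (may be negative, <= 100)."""
    cfg = score_config(config)["msdps"]
    parts: dict[str, pd.Series] = {}
    pyramid_kcal = pd.Series(0.0, index=df.index)
    for name, comp in cfg["components"].items():
        grams = sum((fg(df, food) for food in comp["foods"]),
                    pd.Series(0.0, index=df.index))
        servings = grams / float(comp["serving_g"])
        parts[name] = msdps_component_score(servings, float(comp["recommended_per_day"]))
        pyramid_kcal = pyramid_kcal + grams * float(comp["kcal_per_g"])
    med_fraction = np.minimum(1.0, pyramid_kcal / energy(df))
    total = sum(parts.values()) / (10.0 * len(cfg["components"])) * 100.0 * med_fraction
    return as_components(total.rename("msdps"), parts, return_components)
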