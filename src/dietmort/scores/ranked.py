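"""Rank-based guideline scores: the Healthy Nordic Food Index and the
(modified, sodium-free) DASH score.

HNFI (0-6): one point per Nordic food consumed above the sex-specific median
(fish and shellfish, cabbage, whole-grain bread, apples and pears, root
vegetables, whole-grain breakfast cereals).

DASH (7-35 modified): sex-specific quintile rank 1-5 for fruit, vegetables,
legumes+nuts, whole grains and low-fat dairy; reversed rank (6 - quintile)
for sugary drinks and red/processed meat.  The sodium component of the
original 8-component score is removed.
"""

from __future__ import annotations

import pandas as pd

from ..cutoffs import CutoffSet, derive_cutoffs
from .base import as_components, fg, legumes_nuts, score_config, whole_grains


def _hnfi_values(df: pd.DataFrame, cfg: dict) -> dict[str, pd.Series]:
    return {name: fg(df, name) for name in cfg["components"]}


def derive_hnfi_cutoffs(df: pd.DataFrame, config: dict | None = None) -> CutoffSet:
    cfg = score_config(config)["hnfi"]
    return derive_cutoffs(df, _hnfi_values(df, cfg), "median", strata=("sex",))


def compute_hnfi(df: pd.DataFrame, cutoffs: CutoffSet | None = None,
                 config: dict | None = None, return_components: bool = False):
    """Healthy Nordic Food Index, integer 0-6 per subject."""
    cfg = score_config(config)["hnfi"]
    vals = _hnfi_values(df, cfg)
    if cutoffs is None:
        cutoffs = derive_cutoffs(df, vals, "median", strata=("sex",))
    parts = {name: cutoffs.assign(df, name, vals[name]) for name in cfg["components"]}
    total = sum(parts.values()).astype(int)
    return as_components(total.rename("hnfi"), parts, return_components)


def _dash_values(df: pd.DataFrame, cfg: dict) -> dict[str, pd.Series]:
    derived = {
        "legumes_nuts": legumes_nuts,
        "whole_grains": whole_grains,
    }
    vals: dict[str, pd.Series] = {}
    for name in cfg["beneficial"] + cfg["harmful"]:
        vals[name] = derived[name](df) if name in derived else fg(df, name)
    return vals


def derive_dash_cutoffs(df: pd.DataFrame, config: dict | None = None) -> CutoffSet:
    cfg = score_config(config)["dash"]
    return derive_cutoffs(df, _dash_values(df, cfg), "quintiles", strata=("sex",))


def compute_dash(df: pd.DataFrame, cutoffs: CutoffSet | None = None,
                 config: dict | None = None, return_components: bool = False):
    """Modified DASH score, integer 7-35 per subject."""
    cfg = score_config(config)["dash"]
    vals = _dash_values(df, cfg)
    if cutoffs is None:
        cutoffs = derive_cutoffs(df, vals, "quintiles", strata=("sex",))
    parts: dict[str, pd.Series] = {}
    for name in cfg["beneficial"]:
        parts[name] = cutoffs.assign(df, name, vals[name]) + 1       # 1..5
    for name in cfg["harmful"]:
        parts[name] = 5 - cutoffs.assign(df, name, vals[name])       # 5..1
    total = sum(parts.values()).astype(int)
    return as_components(total.rename("dash"), parts, return_components)
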