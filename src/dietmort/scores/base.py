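"""Shared helpers for the diet-quality scorers.

All scorers are vectorised over a cohort DataFrame following the generator's
column contract: food groups as ``foodgroup_<name>_g`` (g/day), nutrients as
``nutrient_<name>`` and total energy as ``energy_kcal``.  Percent-of-energy
conversions use 9 kcal/g fat, 4 kcal/g protein and carbohydrate, 7 kcal/g
ethanol.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..config import load_score_config
from ..errors import DataError, MissingComponentError

ENERGY_FACTORS = {"fat": 9.0, "protein": 4.0, "carbohydrate": 4.0, "ethanol": 7.0}


def fg(df: pd.DataFrame, name: str) -> pd.Series:
    """Food-group intake in g/day."""
    col = f"foodgroup_{name}_g"
    if col not in df.columns:
        raise MissingComponentError(f"food group column {col!r} is missing")
    return df[col].astype(float)


def nut(df: pd.DataFrame, name: str) -> pd.Series:
    """Nutrient intake (unit in the column name)."""
    col = f"nutrient_{name}"
    if col not in df.columns:
        raise MissingComponentError(f"nutrient column {col!r} is missing")
    return df[col].astype(float)


def energy(df: pd.DataFrame) -> pd.Series:
    if "energy_kcal" not in df.columns:
        raise MissingComponentError("column 'energy_kcal' is missing")
    e = df["energy_kcal"].astype(float)
    if (e <= 0).any():
        raise DataError("energy_kcal must be positive for all subjects")
    return e


def pct_energy(df: pd.DataFrame, nutrient_name: str, macro: str) -> pd.Series:
    """Percent of total energy contributed by a macronutrient (grams)."""
    return nut(df, nutrient_name) * ENERGY_FACTORS[macro] / energy(df) * 100.0


def lifestyle(df: pd.DataFrame, col: str) -> pd.Series:
    if col not in df.columns:
        raise MissingComponentError(f"lifestyle column {col!r} is missing")
    return df[col]


def require_sex(df: pd.DataFrame) -> pd.Series:
    return lifestyle(df, "sex")


def fruit_veg(df: pd.DataFrame) -> pd.Series:
    return fg(df, "fruit") + fg(df, "vegetables")


def whole_grains(df: pd.DataFrame) -> pd.Series:
    return fg(df, "whole_grain_bread") + fg(df, "whole_grain_cereals")


def legumes_nuts(df: pd.DataFrame) -> pd.Series:
    return fg(df, "legumes") + fg(df, "nuts")


def score_config(config: dict | None) -> dict:
    return load_score_config() if config is None else config


def in_window(values: pd.Series, window) -> pd.Series:
    lo, hi = float(window[0]), float(window[1])
    return (values >= lo) & (values <= hi)


def as_components(total: pd.Series, parts: dict[str, pd.Series],
                  return_components: bool):
    if not return_components:
        return total
    comp = pd.DataFrame(parts, index=total.index)
    return total, comp


def safe_ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    """num/den with zero denominators mapped to +inf (0/0 -> 0)."""
    index = num.index if isinstance(num, pd.Series) else None
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(len(num), np.inf)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    out[(~nz) & (num == 0)] = 0.0
    return pd.Series(out, index=index)
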