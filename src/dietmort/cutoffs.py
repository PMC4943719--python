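"""Population-dependent quantile cut-offs.

Several of the diet-quality indices score a subject's intake relative to the
cohort at hand rather than against fixed targets: above/below the sex-specific
median, sex-specific tertiles or quintiles, center-specific deciles.  This
module derives those boundaries within strata and assigns subjects to bins.

Conventions (fixed so that hand oracles are reproducible):

* quantiles use the linear-interpolation sample definition
  (``numpy.quantile`` with its default method);
* the tie rule is "at or above a boundary counts as the higher category",
  so a value exactly equal to the median scores as *above* the median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateCutoffWarning, EmptyStratumError

#: interior quantile probabilities for each named specification
QUANTILE_SPECS: dict[str, np.ndarray] = {
    "median": np.array([0.5]),
    "tertiles": np.array([1 / 3, 2 / 3]),
    "quartiles": np.array([0.25, 0.5, 0.75]),
    "quintiles": np.array([0.2, 0.4, 0.6, 0.8]),
    "deciles": np.arange(1, 10) / 10.0,
}


@dataclass
class CutoffSet:
    """Quantile boundaries per (component, stratum).

    Parameters
    ----------
    quantile_spec
        One of ``median``, ``tertiles``, ``quartiles``, ``quintiles``,
        ``deciles``.
    strata_cols
        Column names defining the stratification (e.g. ``("sex",)`` or
        ``("sex", "center")``).  Empty tuple means one cohort-wide stratum.
    boundaries
        Mapping ``(component, stratum_key) -> ascending boundary array``.
    """

    quantile_spec: str
    strata_cols: tuple[str, ...]
    boundaries: dict[tuple, np.ndarray] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(QUANTILE_SPECS[self.quantile_spec]) + 1

    def stratum_key(self, row_or_df):
        if not self.strata_cols:
            return ()
        if isinstance(row_or_df, pd.DataFrame):
            return list(zip(*(row_or_df[c] for c in self.strata_cols)))
        return tuple(row_or_df[c] for c in self.strata_cols)

    def assign(self, df: pd.DataFrame, component: str, values) -> pd.Series:
        """Bin ``values`` (aligned with ``df``) for ``component``.

        Returns 0-based integer bins, 0 = lowest category.  A value at or
        above a boundary falls in the higher bin.
        """
        values = np.asarray(values, dtype=float)
        out = np.empty(len(values), dtype=np.int64)
        if not self.strata_cols:
            out[:] = _bin(values, self._bounds(component, ()))
        else:
            grouper = df.groupby(list(self.strata_cols), observed=True, sort=False)
            for key, idx in grouper.indices.items():
                key = key if isinstance(key, tuple) else (key,)
                out[idx] = _bin(values[idx], self._bounds(component, key))
        return pd.Series(out, index=df.index, name=component)

    def _bounds(self, component: str, key: tuple) -> np.ndarray:
        try:
            return self.boundaries[(component, key)]
        except KeyError:
            raise DataError(
                f"no cut-offs derived for component {component!r} in stratum {key!r}"
            ) from None


def _bin(values: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    # number of boundaries that are <= value  ==  "at or above counts higher"
    return np.searchsorted(bounds, values, side="right")


def derive_cutoffs(
    df: pd.DataFrame,
    components: dict[str, "pd.Series | np.ndarray"],
    quantile_spec: str,
    strata: tuple[str, ...] = (),
) -> CutoffSet:
    """Derive within-stratum quantile boundaries on the cohort at hand.

    Parameters
    ----------
    df
        Cohort table; only the strata columns are read.
    components
        Mapping component name -> value vector aligned with ``df`` (this keeps
        derived variables like nutrient ratios out of the table contract).
    quantile_spec
        Named quantile scheme, see :data:`QUANTILE_SPECS`.
    strata
        Stratification columns; every stratum must be non-empty.
    """
    if quantile_spec not in QUANTILE_SPECS:
        raise DataError(
            f"unknown quantile_spec {quantile_spec!r}; expected one of "
            f"{sorted(QUANTILE_SPECS)}"
        )
    probs = QUANTILE_SPECS[quantile_spec]
    cs = CutoffSet(quantile_spec=quantile_spec, strata_cols=tuple(strata))

    if strata:
        grouper = df.groupby(list(strata), observed=True, sort=False)
        groups = {
            (k if isinstance(k, tuple) else (k,)): idx
            for k, idx in grouper.indices.items()
        }
    else:
        groups = {(): np.arange(len(df))}

    for key, idx in groups.items():
        if len(idx) == 0:  # pragma: no cover - groupby never yields empty
            raise EmptyStratumError(f"stratum {key!r} is empty")
        for name, vec in components.items():
            vals = np.asarray(vec, dtype=float)[idx]
            if len(vals) == 0:
                raise EmptyStratumError(
                    f"stratum {key!r} has no subjects for component {name!r}"
                )
            if np.nanmax(vals) == np.nanmin(vals):
                warnings.warn(
                    f"component {name!r} is constant in stratum {key!r}; "
                    "all subjects fall in a single bin",
                    DegenerateCutoffWarning,
                    stacklevel=2,
                )
            cs.boundaries[(name, key)] = np.quantile(vals, probs)
    return cs
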