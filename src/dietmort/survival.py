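"""Stratified Cox proportional-hazards models for score-mortality association.

Two covariate sets are used throughout: Model 1 adjusts for age only; Model 2
adds BMI (continuous), smoking (3 categories), physical activity (4
categories) and education (4 categories).  Both stratify the baseline hazard
by sex and study center.  Scores that already contain lifestyle components
get reduced Model-2 sets: the total healthy-lifestyle index is adjusted for
education only, the WCRF score for education and smoking.  An
energy-adjusted variant adds total energy intake (kcal/day) to Model 2.

The exposure enters either as the within-stratum standardized score (the
coefficient is then the log hazard ratio per SD) or as quartile indicators
with the lowest quartile as reference plus a linear-trend test that re-enters
the quartile index 1-4 as a single continuous term (Wald test).

The partial-likelihood optimisation is delegated to
:class:`lifelines.CoxPHFitter` (Efron tie handling); this module owns design
assembly, stratification and result extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as LLConvergenceError

from .errors import ConvergenceError, DataError
from .prep import OUTCOMES, outcome_events

log = logging.getLogger(__name__)

CATEGORICAL_BASELINES = {
    "smoking": "never",
    "education": "none_primary",
    "pa_cambridge": "inactive",
}

#: scores whose lifestyle components restrict the Model-2 covariate set
REDUCED_MODEL2 = {
    "hli_total": ["education"],
    "wcrf": ["education", "smoking"],
}
FULL_MODEL2 = ["bmi", "smoking", "pa_cambridge", "education"]


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one Cox fit."""

    outcome: str = "all_cause"
    score: str | None = None          # score column, e.g. "mds"; None = baseline
    exposure_type: str = "z"          # "z" or "quartile"
    model: int | str = 1              # 1, 2 or "energy"
    strata: tuple[str, ...] = ("sex", "center")
    ties: str = "efron"
    extra_covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise DataError(f"unknown outcome {self.outcome!r}")
        if self.model not in (1, 2, "energy"):
            raise DataError(f"model must be 1, 2 or 'energy', got {self.model!r}")
        if self.ties != "efron":
            raise DataError("only Efron tie handling is supported")
        if self.exposure_type not in ("z", "quartile"):
            raise DataError(f"exposure_type must be 'z' or 'quartile'")

    @property
    def exposure_col(self) -> str | None:
        if self.score is None:
            return None
        return f"{self.score}_{'z' if self.exposure_type == 'z' else 'q'}"

    def covariates(self) -> list[str]:
        cols = ["age"]
        if self.model in (2, "energy"):
            cols += REDUCED_MODEL2.get(self.score, FULL_MODEL2)
        if self.model == "energy":
            cols.append("energy_kcal")
        cols += list(self.extra_covariates)
        if self.exposure_col in cols or (self.score in cols):
            raise DataError(f"exposure {self.score!r} also appears as a covariate")
        return cols


@dataclass
class CoxFitResult:
    """Extracted results of one stratified Cox fit."""

    spec: ModelSpec
    summary: pd.DataFrame                 # lifelines summary (term-indexed)
    n: int
    n_events: int
    n_dropped: int                        # listwise-deleted rows
    fitter: CoxPHFitter = field(repr=False)
    design_cols: list[str] = field(default_factory=list)
    quartile_hrs: pd.DataFrame | None = None
    trend_p: float | None = None

    @property
    def per_sd_hr(self) -> float:
        return float(self.summary.loc[self.spec.exposure_col, "exp(coef)"])

    @property
    def per_sd_ci(self) -> tuple[float, float]:
        row = self.summary.loc[self.spec.exposure_col]
        return (float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"]))

    def linear_predictor(self, data: pd.DataFrame) -> pd.Series:
        """X @ beta on new data using the fitted coefficients (uncentered)."""
        X = _design_matrix(data, self.design_cols)
        beta = self.fitter.params_.reindex(X.columns)
        if beta.isna().any():
            raise DataError(f"design mismatch: {beta[beta.isna()].index.tolist()}")
        return X @ beta

    def tidy(self) -> pd.DataFrame:
        rows = []
        for term, row in self.summary.iterrows():
            rows.append({
                "outcome": self.spec.outcome, "score": self.spec.score,
                "model": self.spec.model, "term": term,
                "hr": row["exp(coef)"], "lcl": row["exp(coef) lower 95%"],
                "ucl": row["exp(coef) upper 95%"], "p": row["p"],
            })
        out = pd.DataFrame(rows)
        if self.trend_p is not None:
            out["trend_p"] = self.trend_p
        return out


def _design_matrix(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Expand categorical covariates into treatment-coded dummies."""
    parts = []
    for col in cols:
        base = col.split("::")[0]
        if "::" in col:  # already a dummy spec "column::level"
            level: object = col.split("::")[1]
            if data[base].dtype.kind in "iuf":
                level = float(level)
            parts.append((data[base] == level).astype(float).rename(col))
        elif base in CATEGORICAL_BASELINES:
            ref = CATEGORICAL_BASELINES[base]
            for level in sorted(data[base].dropna().unique()):
                if level != ref:
                    parts.append((data[base] == level).astype(float)
                                 .rename(f"{base}::{level}"))
        else:
            parts.append(data[base].astype(float).rename(col))
    return pd.concat(parts, axis=1)


def _fit(data: pd.DataFrame, spec: ModelSpec, exposure_cols: list[str],
         time_col="time_y") -> tuple[CoxPHFitter, pd.DataFrame, int]:
    covs = spec.covariates()
    base_cols = [c.split("::")[0] for c in exposure_cols + covs]
    needed = list(dict.fromkeys(base_cols + list(spec.strata) + [time_col]))
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise DataError(f"columns required for the fit are missing: {missing}")
    events = outcome_events(data, spec.outcome)
    sub = data[needed].assign(_event=events)
    before = len(sub)
    sub = sub.dropna()
    dropped = before - len(sub)
    if dropped:
        log.info("listwise deletion removed %d of %d rows", dropped, before)
    X = _design_matrix(sub, exposure_cols + covs)
    fit_df = pd.concat([sub[[time_col, "_event", *spec.strata]], X], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(fit_df, duration_col=time_col, event_col="_event",
                strata=list(spec.strata))
    except (LLConvergenceError, np.linalg.LinAlgError) as err:
        raise ConvergenceError(f"Cox fit failed for {spec}: {err}") from err
    return cph, X, dropped


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> CoxFitResult:
    """Fit the stratified Cox model of ``spec`` on prepared, truncated data."""
    exposure = [] if spec.score is None else [spec.exposure_col]
    if spec.exposure_type == "quartile" and spec.score is not None:
        return hr_by_quartile_with_trend(data, spec)
    cph, X, dropped = _fit(data, spec, exposure)
    return CoxFitResult(spec=spec, summary=cph.summary, n=int(cph._n_examples),
                        n_events=int(cph.event_observed.sum()), n_dropped=dropped,
                        fitter=cph, design_cols=list(X.columns))


def hr_by_quartile_with_trend(data: pd.DataFrame, spec: ModelSpec) -> CoxFitResult:
    """Quartile HRs (Q1 reference) plus a linear-trend Wald p-value."""
    if spec.score is None:
        raise DataError("quartile analysis requires a score")
    qcol = f"{spec.score}_q"
    if qcol not in data.columns:
        raise DataError(f"quartile column {qcol!r} missing; run assign_quartiles")
    events = outcome_events(data, spec.outcome)
    estimable, empty = [], []
    for q in (2, 3, 4):
        (estimable if events[data[qcol] == q].sum() > 0 else empty).append(q)
    dummies = [f"{qcol}::{q}" for q in estimable]
    qspec = replace(spec, exposure_type="z")  # bypass quartile recursion
    cph, X, dropped = _fit(data, qspec, dummies)
    rows = [{"quartile": 1, "hr": 1.0, "lcl": np.nan, "ucl": np.nan, "p": np.nan}]
    for q in (2, 3, 4):
        term = f"{qcol}::{q}"
        if q in empty:
            rows.append({"quartile": q, "hr": np.nan, "lcl": np.nan,
                         "ucl": np.nan, "p": np.nan})
        else:
            r = cph.summary.loc[term]
            rows.append({"quartile": q, "hr": r["exp(coef)"],
                         "lcl": r["exp(coef) lower 95%"],
                         "ucl": r["exp(coef) upper 95%"], "p": r["p"]})
    trend_cph, _, _ = _fit(data.assign(**{f"{spec.score}_qidx":
                                          data[qcol].astype(float)}),
                           qspec, [f"{spec.score}_qidx"])
    trend_p = float(trend_cph.summary.loc[f"{spec.score}_qidx", "p"])
    return CoxFitResult(spec=spec, summary=cph.summary, n=int(cph._n_examples),
                        n_events=int(cph.event_observed.sum()), n_dropped=dropped,
                        fitter=cph, design_cols=list(X.columns),
                        quartile_hrs=pd.DataFrame(rows), trend_p=trend_p)
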