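"""Country-level random-effects meta-analysis (DerSimonian-Laird).

Cox models (or discrimination statistics) are fitted separately per country
and pooled with inverse-variance random-effects weights.  Heterogeneity is
quantified by Cochran's Q and I^2 = max(0, (Q - df) / Q) * 100; the
between-country variance is the DerSimonian-Laird moment estimator
tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effect
weights w_i = 1/SE_i^2.  Log hazard ratios are pooled on the log scale and
back-transformed for reporting; C statistics are pooled on their own scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DataError
from .evaluate import DiscriminationResult, harrell_c
from .prep import outcome_events
from .survival import CoxFitResult, ModelSpec, fit_model

log = logging.getLogger(__name__)


@dataclass
class StudyEstimate:
    unit: str
    estimate: float      # log-HR or C
    se: float
    n: int
    events: int

    def __post_init__(self):
        if not self.se > 0:
            raise DataError(f"unit {self.unit!r}: SE must be positive")


@dataclass
class MetaResult:
    pooled: float
    se: float
    ci: tuple[float, float]
    tau2: float
    q: float
    i2: float            # percent
    k: int
    weights: pd.DataFrame | None = None


def fit_by_country(data: pd.DataFrame, spec: ModelSpec,
                   country_col: str = "country"
                   ) -> tuple[list[StudyEstimate], list[CoxFitResult]]:
    """One per-SD Cox estimate per country; non-estimable countries (no
    events, or non-converging fits) are flagged and excluded with a log entry."""
    estimates, fits = [], []
    for country, sub in data.groupby(country_col, observed=True):
        events = outcome_events(sub, spec.outcome)
        if events.sum() == 0:
            log.warning("country %s has zero %s events; excluded",
                        country, spec.outcome)
            continue
        country_spec = dc_replace(spec)
        try:
            fit = fit_model(sub, country_spec)
        except ConvergenceError as err:
            log.warning("country %s excluded: %s", country, err)
            continue
        row = fit.summary.loc[spec.exposure_col]
        estimates.append(StudyEstimate(unit=str(country),
                                       estimate=float(row["coef"]),
                                       se=float(row["se(coef)"]),
                                       n=fit.n, events=fit.n_events))
        fits.append(fit)
    if not estimates:
        raise DataError("no country yielded an estimable fit")
    return estimates, fits


def pool_random_effects(estimates: list[StudyEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of the estimates."""
    k = len(estimates)
    if k < 2:
        raise DataError("random-effects pooling needs at least 2 estimates")
    y = np.array([e.estimate for e in estimates])
    se = np.array([e.se for e in estimates])
    w = 1.0 / se**2
    theta_fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - theta_fixed) ** 2))
    df = k - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * y) / np.sum(w_re))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_re)))
    zcrit = stats.norm.ppf(0.975)
    weights = pd.DataFrame({
        "unit": [e.unit for e in estimates], "estimate": y, "se": se,
        "weight": w_re / np.sum(w_re),
        "lcl": y - zcrit * se, "ucl": y + zcrit * se,
    })
    return MetaResult(pooled=pooled, se=pooled_se,
                      ci=(pooled - zcrit * pooled_se, pooled + zcrit * pooled_se),
                      tau2=float(tau2), q=q, i2=float(i2), k=k, weights=weights)


def pool_cstatistics(per_country: dict[str, DiscriminationResult]) -> MetaResult:
    """Pool per-country discrimination results (C with SE) by random effects."""
    estimates = [StudyEstimate(unit=country, estimate=res.c, se=res.se,
                               n=0, events=0)
                 for country, res in per_country.items()
                 if res.se is not None and res.se > 0]
    return pool_random_effects(estimates)


def country_cstatistics(data: pd.DataFrame, spec: ModelSpec,
                        country_col: str = "country",
                        time_col: str = "time_y"
                        ) -> dict[str, DiscriminationResult]:
    """Fit the model per country and compute Harrell's C with jackknife SE."""
    out = {}
    for country, sub in data.groupby(country_col, observed=True):
        events = outcome_events(sub, spec.outcome)
        if events.sum() == 0:
            log.warning("country %s has zero events; skipped", country)
            continue
        try:
            fit = fit_model(sub, spec)
        except ConvergenceError as err:
            log.warning("country %s skipped: %s", country, err)
            continue
        lp = fit.linear_predictor(sub)
        out[str(country)] = harrell_c(sub[time_col], events, lp,
                                      se_method="jackknife")
    return out
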