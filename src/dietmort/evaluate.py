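"""Predictive performance of the mortality models: discrimination
(Harrell's C), 10-year risk predictions from stratified Cox fits, and
calibration (decile table, predicted-to-observed ratio, calibration slope).

Harrell's C is computed over *usable* pairs — pairs whose survival ordering
is established despite censoring: the earlier time must carry an event (a
censored subject tied with an event counts as surviving longer).  Pairs of
events at identical times are not usable.  C = (concordant + 0.5 * tied
predictions) / usable; 0.5 is chance, 1 perfect.  The standard error is a
leave-one-subject-out jackknife computed from per-subject pair aggregates.

Predicted 10-year risk uses the per-stratum Breslow baseline cumulative
hazard: risk = 1 - exp(-H0_s(10) * exp(lp)).  Observed risk within deciles
of predicted risk is one minus the Kaplan-Meier survivor estimate at the
horizon (a raw event fraction is available by flag); the calibration slope
is the Cox coefficient of the linear predictor re-entered as the sole
covariate on the evaluation data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .errors import ConvergenceError, DataError
from .prep import outcome_events
from .survival import CoxFitResult

__all__ = ["DiscriminationResult", "CalibrationResult", "harrell_c",
           "predict_10y_risk", "calibration_table", "calibration_slope",
           "compare_models"]


@dataclass
class DiscriminationResult:
    c: float                 # reported on the [0.5, 1] convention
    c_raw: float             # orientation-sensitive value in [0, 1]
    se: float | None
    n_usable_pairs: int
    delta_vs_baseline: float | None = None


@dataclass
class CalibrationResult:
    table: pd.DataFrame      # bin, n, mean_predicted, observed, ratio
    overall_ratio: float
    slope: float | None = None


def harrell_c(times, events, risk_scores, se_method: str = "none",
              _chunk: int = 256) -> DiscriminationResult:
    """Concordance between risk scores and censored survival times.

    Higher risk scores are expected for shorter survival.  ``se_method`` is
    ``"none"`` or ``"jackknife"`` (leave one subject out, exact, computed
    from per-subject concordant/usable pair counts).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    r = np.asarray(risk_scores, dtype=float)
    if not (len(t) == len(e) == len(r)):
        raise DataError("times, events and risk_scores must have equal length")
    n = len(t)
    num_s = np.zeros(n)      # concordance numerator contributions per subject
    use_s = np.zeros(n)      # usable-pair counts per subject
    event_idx = np.flatnonzero(e == 1)
    censored = e == 0
    for i in event_idx:
        usable = (t > t[i]) | ((t == t[i]) & censored)
        if not usable.any():
            continue
        ru = r[usable]
        score = np.where(r[i] > ru, 1.0, np.where(r[i] == ru, 0.5, 0.0))
        num_s[i] += score.sum()
        use_s[i] += usable.sum()
        num_s[usable] += score   # pair indices are unique within one event
        use_s[usable] += 1.0
    usable_total = use_s.sum() / 2.0
    if usable_total == 0:
        raise DataError("no usable pairs (no events, or all ties)")
    num_total = num_s.sum() / 2.0
    c_raw = num_total / usable_total
    se = None
    if se_method == "jackknife":
        with np.errstate(invalid="ignore"):
            c_loo = (num_total - num_s) / (usable_total - use_s)
        c_loo = np.where(usable_total - use_s > 0, c_loo, c_raw)
        se = float(np.sqrt((n - 1) / n * np.sum((c_loo - c_loo.mean()) ** 2)))
    elif se_method != "none":
        raise DataError(f"unknown se_method {se_method!r}")
    return DiscriminationResult(c=float(max(c_raw, 1.0 - c_raw)),
                                c_raw=float(c_raw), se=se,
                                n_usable_pairs=int(round(usable_total)))


def breslow_baseline_cumhaz(times, events, lp, horizon: float) -> float:
    """Breslow estimate of the baseline cumulative hazard at ``horizon``:
    sum over event times t_k <= horizon of d_k / sum_{j at risk} exp(lp_j)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    elp = np.exp(np.asarray(lp, dtype=float))
    order = np.argsort(t)
    t, e, elp = t[order], e[order], elp[order]
    # risk set at time t_k: all with t_j >= t_k  -> reverse cumulative sum
    at_risk = np.cumsum(elp[::-1])[::-1]
    h0 = 0.0
    k = 0
    while k < len(t):
        j = k
        d = 0
        while j < len(t) and t[j] == t[k]:
            d += e[j]
            j += 1
        if d > 0 and t[k] <= horizon:
            h0 += d / at_risk[k]
        k = j
    return h0


def predict_10y_risk(fit: CoxFitResult, data: pd.DataFrame,
                     train: pd.DataFrame | None = None,
                     horizon: float = 10.0,
                     time_col: str = "time_y") -> pd.DataFrame:
    """Per-subject predicted event probability by ``horizon`` years.

    The baseline cumulative hazard is estimated per stratum (Breslow) on
    ``train`` (default: ``data`` itself, i.e. apparent performance) with the
    fit's linear predictor; strata present in ``data`` but absent from the
    training table are an error.
    """
    train = data if train is None else train
    strata = list(fit.spec.strata)
    lp_train = fit.linear_predictor(train)
    events = outcome_events(train, fit.spec.outcome)
    h0 = {}
    for key, idx in train.groupby(strata, observed=True).indices.items():
        h0[key] = breslow_baseline_cumhaz(
            train[time_col].to_numpy()[idx], events.to_numpy()[idx],
            lp_train.to_numpy()[idx], horizon)
    lp = fit.linear_predictor(data)
    keys = list(map(tuple, data[strata].itertuples(index=False, name=None)))
    keys = [k if len(k) > 1 else k[0] for k in keys]
    missing = {k for k in keys if k not in h0}
    if missing:
        raise DataError(f"strata absent from the training data: {sorted(missing)}")
    h0_vec = np.array([h0[k] for k in keys])
    risk = 1.0 - np.exp(-h0_vec * np.exp(lp.to_numpy()))
    out = pd.DataFrame({"linear_predictor": lp, "risk": risk}, index=data.index)
    if "subject_id" in data.columns:
        out.insert(0, "subject_id", data["subject_id"])
    return out


def calibration_table(predictions, times, events, horizon: float = 10.0,
                      bins: int = 10, observed: str = "km") -> CalibrationResult:
    """Observed vs predicted risk per quantile bin of predicted risk.

    ``observed`` is ``"km"`` (1 - Kaplan-Meier at the horizon, respects
    censoring) or ``"raw"`` (crude event fraction).  Bins that cannot be
    formed because of mass ties are merged with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("predicted risks must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    try:
        labels = pd.qcut(p, bins, labels=False, duplicates="raise")
    except ValueError:
        warnings.warn("tied predicted risks: merging calibration bins")
        labels = pd.qcut(p, bins, labels=False, duplicates="drop")
    labels = np.asarray(labels, dtype=float)
    labels[np.isnan(labels)] = 0.0   # fully tied predictions: one bin
    rows = []
    for b in np.unique(labels):
        m = labels == b
        rows.append({
            "bin": int(b) + 1, "n": int(m.sum()),
            "mean_predicted": float(p[m].mean()),
            "observed": _observed_risk(t[m], e[m], horizon, observed),
        })
    table = pd.DataFrame(rows)
    table["ratio"] = table["mean_predicted"] / table["observed"].replace(0, np.nan)
    overall = _observed_risk(t, e, horizon, observed)
    return CalibrationResult(table=table,
                             overall_ratio=float(p.mean() / overall))


def _observed_risk(t, e, horizon, method) -> float:
    if method == "raw":
        return float(np.mean((e == 1) & (t <= horizon)))
    if method != "km":
        raise DataError(f"unknown observed-risk method {method!r}")
    km = KaplanMeierFitter()
    km.fit(t, e)
    return float(1.0 - km.predict(horizon))


def calibration_slope(fit: CoxFitResult, data: pd.DataFrame,
                      time_col: str = "time_y") -> float:
    """Cox coefficient of the fitted linear predictor re-entered as the sole
    covariate on evaluation data (1 = neither over- nor under-fitting)."""
    lp = fit.linear_predictor(data)
    events = outcome_events(data, fit.spec.outcome)
    df = pd.DataFrame({time_col: data[time_col], "_event": events, "_lp": lp})
    for s in fit.spec.strata:
        df[s] = data[s]
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col="_event",
                strata=list(fit.spec.strata))
    except Exception as err:  # lifelines raises several exception types
        raise ConvergenceError(f"calibration-slope refit failed: {err}") from err
    return float(cph.params_["_lp"])


def compare_models(baseline_fit: CoxFitResult, augmented_fit: CoxFitResult,
                   data: pd.DataFrame, time_col: str = "time_y",
                   se_method: str = "none") -> DiscriminationResult:
    """C(augmented) - C(baseline) on the same subjects and usable-pair set."""
    if baseline_fit.spec.outcome != augmented_fit.spec.outcome:
        raise DataError("fits compare different outcomes")
    events = outcome_events(data, augmented_fit.spec.outcome)
    res_b = harrell_c(data[time_col], events, baseline_fit.linear_predictor(data),
                      se_method=se_method)
    res_a = harrell_c(data[time_col], events, augmented_fit.linear_predictor(data),
                      se_method=se_method)
    res_a.delta_vs_baseline = res_a.c_raw - res_b.c_raw
    return res_a
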