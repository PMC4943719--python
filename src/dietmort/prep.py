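"""Cohort construction: exclusions, follow-up truncation, within-stratum
score standardization and quartile assignment.

The analysis cohort excludes subjects with prevalent cancer, myocardial
infarction, angina, stroke or diabetes; follow-up is truncated at 10 years;
scores are standardized and ranked into quartiles separately for men and
women within each study center so hazard ratios are comparable across scores.
Cause-specific analyses censor deaths from competing causes at the death
time (cause-specific hazard approach).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .cutoffs import derive_cutoffs
from .errors import DataError

log = logging.getLogger(__name__)

PREVALENT_FLAGS = ["prev_cancer", "prev_mi", "prev_angina", "prev_stroke",
                   "prev_diabetes"]

OUTCOMES = ["all_cause", "cvd", "cancer", "obesity_cancer"]


def apply_exclusions(cohort: pd.DataFrame,
                     flags: list[str] = PREVALENT_FLAGS) -> tuple[pd.DataFrame, dict]:
    """Remove subjects with any prevalent-disease flag.

    Returns the retained cohort and an exclusion log
    ``{flag: count flagged, "excluded": total removed, "retained": n}``
    (subjects may carry several flags; counts are per flag).
    """
    missing = [f for f in flags if f not in cohort.columns]
    if missing:
        raise DataError(f"prevalent-disease flag columns missing: {missing}")
    any_flag = cohort[flags].any(axis=1)
    counts = {f: int(cohort[f].sum()) for f in flags}
    counts["excluded"] = int(any_flag.sum())
    counts["retained"] = int((~any_flag).sum())
    if counts["retained"] == 0:
        warnings.warn("all subjects excluded by prevalent-disease flags")
    log.info("exclusions: %s", counts)
    return cohort.loc[~any_flag].copy(), counts


def truncate_followup(records: pd.DataFrame, horizon: float = 10.0,
                      time_col: str = "time_y", event_col: str = "event"
                      ) -> pd.DataFrame:
    """Administratively censor everyone still at risk at ``horizon`` years."""
    if horizon <= 0:
        raise DataError("truncation horizon must be positive")
    t = records[time_col].astype(float)
    if (t <= 0).any():
        raise DataError("follow-up times must be positive")
    out = records.copy()
    late = t > horizon
    out.loc[late, time_col] = horizon
    out.loc[late, event_col] = 0
    if "cause" in out.columns:
        out.loc[late, "cause"] = "none"
        if "obesity_related" in out.columns:
            out.loc[late, "obesity_related"] = False
    return out


def outcome_events(records: pd.DataFrame, outcome: str) -> pd.Series:
    """0/1 event indicator for an outcome; competing causes count as censored
    (their death time stays the exit time)."""
    if outcome not in OUTCOMES:
        raise DataError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    event = records["event"].astype(int)
    if outcome == "all_cause":
        return event
    if outcome == "obesity_cancer":
        return ((event == 1) & (records["cause"] == "cancer")
                & records["obesity_related"].astype(bool)).astype(int)
    return ((event == 1) & (records["cause"] == outcome)).astype(int)


def standardize_scores(scores: pd.DataFrame, cohort: pd.DataFrame,
                       score_cols: list[str],
                       strata: tuple[str, ...] = ("sex", "center")
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-stratum z-scores (sample SD, denominator n-1).

    Returns ``(z_table, stats_table)`` where ``z_table`` has one ``<score>_z``
    column per input score and ``stats_table`` reports the per-stratum mean
    and SD used.  A zero-variance stratum is an error naming it.
    """
    df = cohort[list(strata)].join(scores[score_cols])
    grouped = df.groupby(list(strata), observed=True)
    stats_rows = []
    out = pd.DataFrame(index=scores.index)
    for col in score_cols:
        mean = grouped[col].transform("mean")
        sd = grouped[col].transform(lambda s: s.std(ddof=1))
        if (sd.isna() | (sd == 0)).any():
            bad = df.loc[sd.isna() | (sd == 0), list(strata)].drop_duplicates()
            raise DataError(
                f"score {col!r} has zero variance (or a single subject) in "
                f"strata {bad.to_records(index=False).tolist()}")
        out[f"{col}_z"] = (df[col] - mean) / sd
    for key, sub in grouped:
        for col in score_cols:
            stats_rows.append({**dict(zip(strata, key if isinstance(key, tuple)
                                          else (key,))),
                               "score": col, "mean": sub[col].mean(),
                               "sd": sub[col].std(ddof=1), "n": len(sub)})
    return out, pd.DataFrame(stats_rows)


def assign_quartiles(scores: pd.DataFrame, cohort: pd.DataFrame,
                     score_cols: list[str],
                     strata: tuple[str, ...] = ("sex", "center")
                     ) -> pd.DataFrame:
    """Stratum-specific quartile labels 1-4 (ties go to the higher quartile)."""
    df = cohort[list(strata)].copy()
    sizes = df.groupby(list(strata), observed=True).size()
    if (sizes < 4).any():
        raise DataError(
            f"strata too small for quartiles: {sizes[sizes < 4].index.tolist()}")
    out = pd.DataFrame(index=scores.index)
    values = {col: scores[col] for col in score_cols}
    cuts = derive_cutoffs(df, values, "quartiles", strata=strata)
    for col in score_cols:
        q = cuts.assign(df, col, values[col]) + 1
        # a constant stratum is assigned to the reference quartile
        spread = values[col].groupby([df[s] for s in strata]).transform(
            lambda s: s.max() - s.min())
        q = q.where(spread > 0, 1)
        out[f"{col}_q"] = q
    return out


def prepare_cohort(cohort: pd.DataFrame, scores: pd.DataFrame,
                   score_cols: list[str], horizon: float = 10.0,
                   strata: tuple[str, ...] = ("sex", "center")):
    """Exclusions + truncation + standardization + quartiles in one call.

    Returns ``(analysis_table, exclusion_log)`` where the analysis table is
    the retained cohort joined with ``<score>_z`` and ``<score>_q`` columns.
    """
    retained, excl = apply_exclusions(cohort)
    retained = truncate_followup(retained, horizon=horizon)
    sc = scores.loc[retained.index]
    z, _ = standardize_scores(sc, retained, score_cols, strata=strata)
    q = assign_quartiles(sc, retained, score_cols, strata=strata)
    joined = pd.concat([retained, sc[score_cols], z, q], axis=1)
    return joined, excl
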