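"""End-to-end orchestration: simulate (or load) -> score -> prepare -> fit ->
evaluate -> pool, with reproducible on-disk outputs.

Outputs written to the run directory:

* ``cohort.csv`` (when simulated) and ``scores.csv``
* ``hr_table.csv`` — per-SD and quartile hazard ratios with trend p-values
* ``cstatistics.json`` — baseline/Model-1/Model-2 C statistics and deltas
* ``calibration_<score>_<outcome>.csv`` and ``.svg`` — decile tables/plots
* ``meta_hr.csv`` / ``meta_c.csv`` — country-level pooled estimates with I^2
* ``subgroups.csv`` — sex- and age-stratified per-SD fits (when requested)
* ``manifest.json`` — seed, config hash, package version, attrition counts
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import generate_cohort, save_cohort
from .config import load_cohort_config
from .errors import ConvergenceError, DataError
from .evaluate import (calibration_slope, calibration_table, compare_models,
                       harrell_c, predict_10y_risk)
from .meta import country_cstatistics, fit_by_country, pool_cstatistics, \
    pool_random_effects
from .prep import apply_exclusions, outcome_events, truncate_followup
from .prep import assign_quartiles, standardize_scores
from .scores import SCORE_NAMES, score_all
from .survival import CoxFitResult, ModelSpec, fit_model

log = logging.getLogger(__name__)

DEFAULT_RUN = {
    "cohort_csv": None,          # path to an existing cohort; None = simulate
    "n_subjects": 20000,
    "seed": 0,
    "scores": list(SCORE_NAMES),
    "outcomes": ["all_cause"],
    "models": [1, 2],
    "subgroups": [],             # subset of {"sex", "age"}
    "meta_analysis": False,
    "calibration": True,
    "horizon_years": 10.0,
    "out_dir": "dietmort_run",
    "cohort_overrides": {},
}


def _score_columns(requested: list[str]) -> list[str]:
    cols = []
    for s in requested:
        cols += ["hli_diet", "hli_total"] if s == "hli" else [s]
    return cols


def prepare_analysis_table(run_cfg: dict) -> tuple[pd.DataFrame, dict]:
    """Simulate or load the cohort, apply exclusions and truncation, compute
    scores, standardize and quartile them.  Returns (table, attrition log)."""
    horizon = float(run_cfg["horizon_years"])
    if run_cfg.get("cohort_csv"):
        cohort = pd.read_csv(run_cfg["cohort_csv"])
        cohort_cfg = None
    else:
        cohort_cfg = load_cohort_config(overrides={
            "n_subjects": run_cfg["n_subjects"], "seed": run_cfg["seed"],
            **run_cfg.get("cohort_overrides", {})})
        cohort = generate_cohort(cohort_cfg)
    n0 = len(cohort)
    retained, excl = apply_exclusions(cohort)
    retained = truncate_followup(retained, horizon=horizon)
    log.info("cohort: %d simulated/loaded, %d analysed", n0, len(retained))
    score_cols = _score_columns(run_cfg["scores"])
    scores = score_all(retained, scores=run_cfg["scores"])
    z, _ = standardize_scores(scores, retained, score_cols)
    q = assign_quartiles(scores, retained, score_cols)
    table = pd.concat([retained, scores[score_cols], z, q], axis=1)
    attrition = {"input": n0, **excl, "horizon_years": horizon}
    return table, attrition


def fit_all_models(table: pd.DataFrame, run_cfg: dict
                   ) -> tuple[pd.DataFrame, dict[tuple, CoxFitResult]]:
    """Per-SD and quartile fits for every requested score/outcome/model."""
    rows, fits = [], {}
    for outcome in run_cfg["outcomes"]:
        for score in _score_columns(run_cfg["scores"]):
            for model in run_cfg["models"]:
                spec = ModelSpec(outcome=outcome, score=score, model=model)
                try:
                    fit = fit_model(table, spec)
                    qfit = fit_model(table, ModelSpec(
                        outcome=outcome, score=score, model=model,
                        exposure_type="quartile"))
                except ConvergenceError as err:
                    log.warning("skipping %s/%s model %s: %s",
                                outcome, score, model, err)
                    continue
                fits[(outcome, score, model)] = fit
                lcl, ucl = fit.per_sd_ci
                row = {"outcome": outcome, "score": score, "model": model,
                       "n": fit.n, "events": fit.n_events,
                       "hr_per_sd": fit.per_sd_hr, "lcl": lcl, "ucl": ucl,
                       "trend_p": qfit.trend_p}
                for _, qrow in qfit.quartile_hrs.iterrows():
                    qn = int(qrow["quartile"])
                    row[f"hr_q{qn}"] = qrow["hr"]
                rows.append(row)
    return pd.DataFrame(rows), fits


def evaluate_models(table: pd.DataFrame, fits: dict, run_cfg: dict,
                    out_dir: Path | None = None) -> dict:
    """Discrimination for baseline/Model 1/Model 2 and calibration tables."""
    results = {"discrimination": [], "calibration": []}
    horizon = float(run_cfg["horizon_years"])
    for outcome in run_cfg["outcomes"]:
        base = fit_model(table, ModelSpec(outcome=outcome, score=None, model=1))
        events = outcome_events(table, outcome)
        c_base = harrell_c(table["time_y"], events, base.linear_predictor(table))
        results["discrimination"].append(
            {"outcome": outcome, "score": None, "model": "baseline",
             "c": c_base.c, "delta_vs_baseline": 0.0})
        for (oc, score, model), fit in fits.items():
            if oc != outcome:
                continue
            res = compare_models(base, fit, table)
            results["discrimination"].append(
                {"outcome": outcome, "score": score, "model": model,
                 "c": res.c, "delta_vs_baseline": res.delta_vs_baseline})
            if run_cfg.get("calibration") and model == 2:
                pred = predict_10y_risk(fit, table, horizon=horizon)
                cal = calibration_table(pred["risk"], table["time_y"], events,
                                        horizon=horizon)
                cal.slope = calibration_slope(fit, table)
                results["calibration"].append(
                    {"outcome": outcome, "score": score,
                     "overall_ratio": cal.overall_ratio, "slope": cal.slope})
                if out_dir is not None:
                    cal.table.to_csv(
                        out_dir / f"calibration_{score}_{outcome}.csv", index=False)
                    _plot_calibration(cal.table,
                                      out_dir / f"calibration_{score}_{outcome}.svg",
                                      f"{score} / {outcome}")
    return results


def _plot_calibration(table: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    lim = max(table["mean_predicted"].max(), table["observed"].max()) * 1.1
    ax.plot([0, lim], [0, lim], color="grey", lw=0.8, ls="--")
    ax.plot(table["mean_predicted"], table["observed"], "o-", ms=4)
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed risk")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def meta_analyses(table: pd.DataFrame, run_cfg: dict) -> dict:
    """Country-specific Model-2 fits pooled by random effects, for log-HRs
    and C statistics, per requested score and outcome."""
    import numpy as np

    out = {"hr": [], "c": []}
    for outcome in run_cfg["outcomes"]:
        for score in _score_columns(run_cfg["scores"]):
            spec = ModelSpec(outcome=outcome, score=score, model=2)
            try:
                estimates, _ = fit_by_country(table, spec)
                pooled = pool_random_effects(estimates)
            except DataError as err:
                log.warning("meta HR skipped for %s/%s: %s", outcome, score, err)
                continue
            out["hr"].append({"outcome": outcome, "score": score,
                              "pooled_hr": float(np.exp(pooled.pooled)),
                              "lcl": float(np.exp(pooled.ci[0])),
                              "ucl": float(np.exp(pooled.ci[1])),
                              "tau2": pooled.tau2, "i2": pooled.i2,
                              "k": pooled.k})
            try:
                per_country = country_cstatistics(table, spec)
                pooled_c = pool_cstatistics(per_country)
            except DataError as err:
                log.warning("meta C skipped for %s/%s: %s", outcome, score, err)
                continue
            out["c"].append({"outcome": outcome, "score": score,
                             "pooled_c": pooled_c.pooled,
                             "lcl": pooled_c.ci[0], "ucl": pooled_c.ci[1],
                             "i2": pooled_c.i2, "k": pooled_c.k})
    return out


def subgroup_analyses(table: pd.DataFrame, run_cfg: dict) -> pd.DataFrame:
    """Model-2 per-SD fits and C within sex and age (<50 / >=50) subgroups."""
    rows = []
    groups = []
    if "sex" in run_cfg["subgroups"]:
        for sex in ("male", "female"):
            groups.append((f"sex={sex}", table[table["sex"] == sex], ("center",)))
    if "age" in run_cfg["subgroups"]:
        groups.append(("age<50", table[table["age"] < 50], ("sex", "center")))
        groups.append(("age>=50", table[table["age"] >= 50], ("sex", "center")))
    for label, sub, strata in groups:
        for outcome in run_cfg["outcomes"]:
            events = outcome_events(sub, outcome)
            if events.sum() == 0:
                rows.append({"subgroup": label, "outcome": outcome,
                             "score": None, "flag": "no events"})
                continue
            for score in _score_columns(run_cfg["scores"]):
                spec = ModelSpec(outcome=outcome, score=score, model=2,
                                 strata=strata)
                try:
                    fit = fit_model(sub, spec)
                except ConvergenceError as err:
                    rows.append({"subgroup": label, "outcome": outcome,
                                 "score": score, "flag": str(err)})
                    continue
                c = harrell_c(sub["time_y"], events, fit.linear_predictor(sub))
                lcl, ucl = fit.per_sd_ci
                rows.append({"subgroup": label, "outcome": outcome,
                             "score": score, "hr_per_sd": fit.per_sd_hr,
                             "lcl": lcl, "ucl": ucl, "c": c.c,
                             "events": fit.n_events, "flag": ""})
    return pd.DataFrame(rows)


def run_pipeline(run_config: dict | None = None, **overrides) -> dict:
    """Execute the full analysis; returns the result bundle and writes it to
    ``out_dir``.  Deterministic given the seed."""
    cfg = {**DEFAULT_RUN, **(run_config or {}), **overrides}
    unknown_scores = set(cfg["scores"]) - set(SCORE_NAMES)
    if unknown_scores:
        raise DataError(f"unknown scores requested: {sorted(unknown_scores)}")
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    table, attrition = prepare_analysis_table(cfg)
    if not cfg.get("cohort_csv"):
        save_cohort(table, str(out_dir / "cohort.csv"))
    hr_table, fits = fit_all_models(table, cfg)
    hr_table.to_csv(out_dir / "hr_table.csv", index=False)
    evaluation = evaluate_models(table, fits, cfg, out_dir=out_dir)
    with open(out_dir / "cstatistics.json", "w") as fh:
        json.dump(evaluation, fh, indent=2, default=float)

    bundle = {"attrition": attrition, "hr_table": hr_table,
              "evaluation": evaluation}
    if cfg["meta_analysis"]:
        meta = meta_analyses(table, cfg)
        pd.DataFrame(meta["hr"]).to_csv(out_dir / "meta_hr.csv", index=False)
        pd.DataFrame(meta["c"]).to_csv(out_dir / "meta_c.csv", index=False)
        bundle["meta"] = meta
    if cfg["subgroups"]:
        sub = subgroup_analyses(table, cfg)
        sub.to_csv(out_dir / "subgroups.csv", index=False)
        bundle["subgroups"] = sub

    manifest = {
        "package_version": __version__,
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(json.dumps(
            {k: v for k, v in cfg.items() if k != "out_dir"},
            sort_keys=True, default=str).encode()).hexdigest(),
        "attrition": attrition,
        "outputs": sorted(p.name for p in out_dir.iterdir()),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
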