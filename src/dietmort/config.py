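"""Configuration loading and validation.

Two YAML documents ship with the package: ``defaults/scores.yaml`` (score
thresholds, serving conversions, component standards) and
``defaults/cohort.yaml`` (the synthetic-cohort generator).  Users override by
passing a YAML path or a dict of overrides that is deep-merged onto the
defaults.
"""

from __future__ import annotations

import copy
from importlib import resources
from typing import Any, Mapping

import yaml

from .errors import ConfigError

_CACHE: dict[str, dict] = {}


def _load_default(name: str) -> dict:
    if name not in _CACHE:
        text = resources.files("dietmort.defaults").joinpath(f"{name}.yaml").read_text()
        _CACHE[name] = yaml.safe_load(text)
    return copy.deepcopy(_CACHE[name])


#: mappings whose overrides replace the default wholesale instead of merging
#: key by key (a partial country list would otherwise extend the default one)
_REPLACE_KEYS = {"countries", "food_groups", "subgroups", "composition"}


def deep_merge(base: dict, overrides: Mapping[str, Any]) -> dict:
    """Recursively merge ``overrides`` onto ``base`` (returns ``base``)."""
    for key, val in overrides.items():
        if (isinstance(val, Mapping) and isinstance(base.get(key), dict)
                and key not in _REPLACE_KEYS):
            deep_merge(base[key], val)
        else:
            base[key] = copy.deepcopy(val) if isinstance(val, (dict, list)) else val
    return base


def load_score_config(path: str | None = None, overrides: Mapping | None = None) -> dict:
    """Score thresholds and standards; package defaults unless overridden."""
    cfg = yaml.safe_load(open(path)) if path else _load_default("scores")
    if overrides:
        deep_merge(cfg, overrides)
    return cfg


def load_cohort_config(path: str | None = None, overrides: Mapping | None = None) -> dict:
    """Generator configuration; validated before return."""
    cfg = yaml.safe_load(open(path)) if path else _load_default("cohort")
    if overrides:
        deep_merge(cfg, overrides)
    validate_cohort_config(cfg)
    return cfg


def _check(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field}: {msg}")


def validate_cohort_config(cfg: dict) -> None:
    """Raise :class:`ConfigError` naming the offending field."""
    _check(int(cfg["n_subjects"]) >= 1, "n_subjects", "must be >= 1")
    _check(0.0 <= cfg["sex_ratio_female"] <= 1.0, "sex_ratio_female", "must be in [0, 1]")
    _check(cfg["age_sd"] > 0, "age_sd", "must be positive")
    lo, hi = cfg["age_bounds"]
    _check(lo < hi, "age_bounds", "lower bound must be below upper bound")
    _check(bool(cfg["countries"]), "countries", "at least one country required")
    for country, k in cfg["countries"].items():
        _check(int(k) >= 1, f"countries.{country}", "center count must be >= 1")
    for sex, kcal in cfg["energy_mean_by_sex"].items():
        _check(kcal > 0, f"energy_mean_by_sex.{sex}", "must be positive")
    for name, probs in cfg["covariate_frequencies"].items():
        for sex, p in probs.items():
            arr = [float(x) for x in p]
            _check(all(0 <= x <= 1 for x in arr), f"covariate_frequencies.{name}.{sex}",
                   "probabilities must be in [0, 1]")
            _check(sum(arr) > 0, f"covariate_frequencies.{name}.{sex}",
                   "probabilities must not all be zero")
    _check(0.0 <= cfg["breastfed_prob"] <= 1.0, "breastfed_prob", "must be in [0, 1]")
    _check(0.0 <= cfg["obesity_related_flag_prob"] <= 1.0,
           "obesity_related_flag_prob", "must be in [0, 1]")
    for disease, rate in cfg["prevalence_rates"].items():
        _check(0.0 <= rate <= 1.0, f"prevalence_rates.{disease}", "must be in [0, 1]")

    im = cfg["intake_model"]
    for name, spec in im["food_groups"].items():
        _check(spec["mean"] > 0, f"intake_model.food_groups.{name}.mean", "must be positive")
        _check(spec["sdlog"] >= 0, f"intake_model.food_groups.{name}.sdlog",
               "must be non-negative")
    for trip in im["correlations"]:
        _check(len(trip) == 3 and -1.0 < float(trip[2]) < 1.0,
               "intake_model.correlations", f"bad entry {trip!r}")
    for agg, sub in im["subgroups"].items():
        _check(agg in im["food_groups"], f"intake_model.subgroups.{agg}",
               "aggregate not in food_groups")
        total = sum(p["fraction"] for p in sub["parts"].values())
        _check(abs(total - 1.0) < 1e-6, f"intake_model.subgroups.{agg}",
               f"part fractions must sum to 1 (got {total})")
        _check(sub["concentration"] > 0, f"intake_model.subgroups.{agg}.concentration",
               "must be positive")

    hz = cfg["hazards"]
    for cause in hz["causes"]:
        _check(hz["weibull_shape"][cause] > 0, f"hazards.weibull_shape.{cause}",
               "must be positive")
        frac = hz["ten_year_fraction"][cause]
        _check(0.0 < frac < 1.0, f"hazards.ten_year_fraction.{cause}",
               "must be in (0, 1)")
    _check(int(hz["calibration_n"]) >= 1000, "hazards.calibration_n", "must be >= 1000")
    for h in cfg["censoring"]["horizons_cycle"]:
        _check(h > 0, "censoring.horizons_cycle", "horizons must be positive")
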