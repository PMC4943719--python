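"""The ten a-priori diet-quality scores.

``score_all`` computes every score on a cohort table; individual
``compute_*`` functions are re-exported for direct use.  Scores whose
cut-offs are population dependent (MDS, rMED, HNFI, DASH, HLI) derive them
from the cohort at hand unless a pre-computed cut-off set is supplied.
"""

from __future__ import annotations

import pandas as pd

from .base import score_config
from .guideline import compute_dqi_i, compute_hei2010, compute_who_hdi, hei2010_max_points
from .lifestyle import compute_hli, compute_wcrf
from .medit import compute_mds, compute_msdps, compute_rmed
from .ranked import compute_dash, compute_hnfi

__all__ = [
    "SCORE_COLUMNS", "score_all",
    "compute_mds", "compute_rmed", "compute_msdps", "compute_hnfi",
    "compute_dash", "compute_who_hdi", "compute_dqi_i", "compute_hei2010",
    "compute_hli", "compute_wcrf", "hei2010_max_points", "score_ranges",
]

#: columns produced by score_all, in output order
SCORE_COLUMNS = ["mds", "rmed", "msdps", "dqi_i", "hnfi", "hei2010",
                 "who_hdi", "dash", "hli_diet", "hli_total", "wcrf"]

#: the ten score names as requested on the command line (hli covers both)
SCORE_NAMES = ["mds", "rmed", "msdps", "dqi_i", "hnfi", "hei2010",
               "who_hdi", "dash", "hli", "wcrf"]


def score_ranges(config: dict | None = None) -> dict[str, tuple[float, float]]:
    """Declared (min, max) range per score column under the configuration."""
    return {
        "mds": (0, 9), "rmed": (0, 18), "msdps": (-float("inf"), 100),
        "dqi_i": (0, 94), "hnfi": (0, 6),
        "hei2010": (0, hei2010_max_points(config)),
        "who_hdi": (0, 7), "dash": (7, 35),
        "hli_diet": (0, 63), "hli_total": (0, 20), "wcrf": (0, 7),
    }


def score_all(cohort: pd.DataFrame, config: dict | None = None,
              scores: list[str] | None = None,
              return_components: bool = False):
    """Compute the requested scores (default: all ten) for every subject.

    Returns a wide DataFrame (one row per subject) and, when
    ``return_components`` is set, a long-format component table
    ``(subject_id, score, component, points)``.
    """
    config = score_config(config)
    wanted = list(SCORE_NAMES) if scores is None else list(scores)
    unknown = set(wanted) - set(SCORE_NAMES)
    if unknown:
        raise ValueError(f"unknown scores requested: {sorted(unknown)}")

    if cohort.empty:
        cols = [c for c in SCORE_COLUMNS
                if c.split("_")[0] in {w.split("_")[0] for w in wanted} or c in wanted]
        out = pd.DataFrame(columns=["subject_id", *cols])
        return (out, pd.DataFrame(columns=["subject_id", "score", "component",
                                           "points"])) if return_components else out

    funcs = {
        "mds": compute_mds, "rmed": compute_rmed, "msdps": compute_msdps,
        "dqi_i": compute_dqi_i, "hnfi": compute_hnfi, "hei2010": compute_hei2010,
        "who_hdi": compute_who_hdi, "dash": compute_dash, "wcrf": compute_wcrf,
    }
    out = pd.DataFrame(index=cohort.index)
    if "subject_id" in cohort.columns:
        out["subject_id"] = cohort["subject_id"]
    long_parts = []
    for name in wanted:
        if name == "hli":
            result = compute_hli(cohort, config=config,
                                 return_components=return_components)
            diet, total = result[0], result[1]
            out["hli_diet"], out["hli_total"] = diet, total
            if return_components:
                long_parts.append(("hli", result[2]))
            continue
        result = funcs[name](cohort, config=config,
                             return_components=return_components)
        if return_components:
            out[name] = result[0]
            long_parts.append((name, result[1]))
        else:
            out[name] = result

    if not return_components:
        return out
    frames = []
    sid = cohort["subject_id"] if "subject_id" in cohort.columns \
        else pd.Series(cohort.index, index=cohort.index)
    for score_name, comp in long_parts:
        melted = comp.assign(subject_id=sid).melt(
            id_vars="subject_id", var_name="component", value_name="points")
        melted.insert(1, "score", score_name)
        frames.append(melted)
    return out, pd.concat(frames, ignore_index=True)
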