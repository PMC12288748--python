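"""Citizen-science consensus scoring and its link to pattern measurements.

Volunteers assign each turtle up to four of nine binary pattern categories.
Per turtle and category, the consensus proportion is the majority-vote
agreement max(#0, #1)/n — a value in [0.5, 1], with ties scoring exactly
0.5. The overall consensus of a turtle is the arithmetic mean of its nine
category proportions and serves as an inverse proxy for pattern complexity:
patterns everyone categorizes the same way are simple, patterns that split
the voters are complex. Consensus scores can then be correlated (Pearson)
with the 19 pattern measurements, with Benjamini–Hochberg adjustment and a
Cook's-distance screen for single influential turtles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .fixtures import SURVEY_CATEGORIES
from .measures import MEASURE_NAMES
from .variation import bh_adjust

logger = logging.getLogger(__name__)

MAX_CATEGORIES_PER_TURTLE = 4


def category_consensus(votes) -> float:
    """Majority-vote agreement for one (turtle, category): max(#0, #1)/n.

    Six '0's and four '1's give 0.60; unanimity gives 1.0; an even split
    gives exactly 0.5.
    """
    v = np.asarray(list(votes), dtype=float)
    if v.size == 0:
        raise ValueError("empty vote list")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("votes must be binary 0/1")
    ones = v.sum()
    return float(max(ones, v.size - ones) / v.size)


def overall_consensus(category_proportions) -> float:
    """Arithmetic mean of the nine category consensus proportions."""
    props = dict(category_proportions)
    missing = [c for c in SURVEY_CATEGORIES if c not in props]
    if missing:
        raise ValueError(f"missing category column(s): {missing}")
    return float(np.mean([props[c] for c in SURVEY_CATEGORIES]))


@dataclass
class ConsensusResult:
    """Per-turtle and per-category consensus plus distribution summaries."""

    per_turtle: pd.DataFrame  # turtle_id, the 9 categories, overall
    per_category: pd.Series  # mean consensus per category across turtles
    summary: dict = field(default_factory=dict)


def read_survey(path_or_df) -> pd.DataFrame:
    """Read a survey as a long-format DataFrame (turtle_id, volunteer,
    category, vote).

    Accepts either the long dialect directly or a wide CSV with a
    turtle_id column and ``volunteer:category`` binary columns. Blank cells
    are read as 0 ("category does not apply"); the number of blanks is
    logged.
    """
    df = pd.read_csv(path_or_df) if not isinstance(path_or_df, pd.DataFrame) else path_or_df.copy()
    if {"turtle_id", "volunteer", "category", "vote"}.issubset(df.columns):
        long = df[["turtle_id", "volunteer", "category", "vote"]].copy()
    else:
        if "turtle_id" not in df.columns:
            raise ValueError("survey needs a turtle_id column")
        vote_cols = [c for c in df.columns if ":" in c]
        if not vote_cols:
            raise ValueError("wide survey needs 'volunteer:category' columns")
        long = df.melt(id_vars="turtle_id", value_vars=vote_cols,
                       var_name="vc", value_name="vote")
        long[["volunteer", "category"]] = long["vc"].str.split(":", n=1, expand=True)
        long = long.drop(columns="vc")
    n_blank = int(long["vote"].isna().sum())
    if n_blank:
        logger.info("survey: %d blank cells read as 0", n_blank)
    long["vote"] = long["vote"].fillna(0).astype(int)
    unknown = set(long["category"]) - set(SURVEY_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown survey categories: {sorted(unknown)}")
    over = (
        long.groupby(["turtle_id", "volunteer"])["vote"].sum()
        .loc[lambda s: s > MAX_CATEGORIES_PER_TURTLE]
    )
    if len(over):
        logger.warning(
            "%d (turtle, volunteer) pairs mark more than %d categories",
            len(over), MAX_CATEGORIES_PER_TURTLE,
        )
    return long


def consensus_table(survey, cut_low: float = 0.70, cut_high: float = 0.80) -> ConsensusResult:
    """Consensus proportions for every turtle and category.

    Returns per-turtle category proportions and overall scores, per-category
    means across turtles, and distribution summaries (mean, sd, min, max,
    counts below ``cut_low`` / above ``cut_high``).
    """
    long = read_survey(survey)
    props = (
        long.groupby(["turtle_id", "category"])["vote"]
        .apply(lambda v: category_consensus(v.to_numpy()))
        .unstack("category")
    )
    missing = [c for c in SURVEY_CATEGORIES if c not in props.columns]
    if missing:
        raise ValueError(f"survey lacks categories: {missing}")
    props = props[list(SURVEY_CATEGORIES)]
    per_turtle = props.copy()
    per_turtle["overall"] = props.mean(axis=1)
    overall = per_turtle["overall"]
    summary = {
        "n_turtles": int(len(per_turtle)),
        "mean": float(overall.mean()),
        "sd": float(overall.std(ddof=1)) if len(overall) > 1 else float("nan"),
        "min": float(overall.min()),
        "max": float(overall.max()),
        f"n_below_{cut_low:g}": int((overall < cut_low).sum()),
        f"n_above_{cut_high:g}": int((overall > cut_high).sum()),
    }
    return ConsensusResult(
        per_turtle=per_turtle.reset_index(),
        per_category=props.mean(axis=0),
        summary=summary,
    )


def correlate_measures(
    consensus: ConsensusResult,
    measures: pd.DataFrame,
    view: str = "top",
) -> pd.DataFrame:
    """Pearson correlation of each measurement with the overall consensus.

    Measurements are restricted to ``view`` and averaged over replicates per
    turtle; NaN-valued measurements drop out pairwise. For each measure the
    table reports r, the raw p, the BH-adjusted p across the 19 tests, and
    the maximum Cook's distance from the univariate linear fit of consensus
    on the measure (a distance > 1 flags a single influential turtle).
    """
    cons = consensus.per_turtle.set_index("turtle_id")["overall"]
    m = measures[measures["view"] == view]
    wide = m.groupby(["turtle_id", "measure"])["value"].mean().unstack("measure")
    shared = wide.index.intersection(cons.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 turtles shared between survey and measures")
    wide = wide.loc[shared]
    cons = cons.loc[shared]
    rows = []
    for meas in MEASURE_NAMES:
        if meas not in wide.columns:
            continue
        x = wide[meas]
        ok = np.isfinite(x) & np.isfinite(cons)
        xv, yv = x[ok].to_numpy(), cons[ok].to_numpy()
        if len(xv) < 3 or np.std(xv) == 0:
            rows.append({"measure": meas, "n": int(len(xv)), "r": np.nan,
                         "p": np.nan, "max_cooks_d": np.nan, "influential": False})
            continue
        r, p = stats.pearsonr(xv, yv)
        fit = sm.OLS(yv, sm.add_constant(xv)).fit()
        cooks = fit.get_influence().cooks_distance[0]
        rows.append(
            {
                "measure": meas,
                "n": int(len(xv)),
                "r": float(r),
                "p": float(p),
                "max_cooks_d": float(np.max(cooks)),
                "influential": bool(np.max(cooks) > 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    return out
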