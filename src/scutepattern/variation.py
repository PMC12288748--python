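"""Measurement noise and between-individual variation.

Repeatability is quantified with coefficients of variation (CV): for the two
duplicate photographs of a view the CV is the absolute pairwise difference
divided by the pair mean (which equals √2 times the two-value sample-sd CV);
for three or more replicates it is the usual sample sd over mean. A measure
whose within-individual CV exceeds 10% of its across-individual CV ratio
threshold is flagged as substantially noisy. The module also provides the
threshold sensitivity analysis (how fractional area responds to moving the
yellowness threshold) and museum-vs-field group comparisons (Welch t on
means, variance-ratio F, and a CV-difference F test) with Benjamini–Hochberg
adjustment across the 19 measures.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .extraction import ExtractionConfig, extract_pattern
from .measures import MEASURE_NAMES, fractional_area

logger = logging.getLogger(__name__)

#: CVs above this are considered substantial variation.
SUBSTANTIAL_CV = 0.10
#: Default test thresholds for the sensitivity analysis, vs baseline 1.10.
DEFAULT_SENSITIVITY_TAUS = (0.90, 1.05, 1.15, 1.30)
DEFAULT_BASELINE_TAU = 1.10


def cv_pairwise(x1: float, x2: float) -> float:
    """|x1 − x2| / mean(x1, x2); NaN when the mean is zero.

    Identity: cv_pairwise(x1, x2) = √2 · cv_standard([x1, x2]).
    """
    m = 0.5 * (x1 + x2)
    if m == 0 or not np.isfinite(m):
        return float("nan")
    return abs((x1 - x2) / m)


def cv_standard(values) -> float:
    """Sample standard deviation (n−1 denominator) over the mean."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


def _group_cv(values: np.ndarray) -> float:
    v = values[np.isfinite(values)]
    if len(v) < 2:
        return float("nan")
    if len(v) == 2:
        return cv_pairwise(v[0], v[1])
    return cv_standard(v)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"turtle_id", "view", "replicate", "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"measure table missing columns: {sorted(missing)}")
    return table


def within_individual_cv(
    table: pd.DataFrame, normalization: str = "pair_mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-to-replicate CV per measure.

    For each (turtle, view, measure) group the CV over replicates is the
    pairwise CV for duplicates and the standard CV for triplicates; groups
    with a single usable replicate are skipped with a log entry. Per
    (measure, view) the CVs are averaged over turtles; per measure, the
    view-averaged mean and the sd across views are reported.

    ``normalization="view_mean"`` selects the alternative convention where
    each pairwise |difference| is normalized by the mean of the measure over
    all individuals within that viewpoint rather than by the pair mean.

    Returns ``(per_view, per_measure)`` DataFrames.
    """
    table = _validate_table(table)
    rows = []
    for (tid, view, meas), grp in table.groupby(["turtle_id", "view", "measure"]):
        v = grp["value"].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            logger.info("skipping %s/%s/%s: <2 usable replicates", tid, view, meas)
            continue
        if normalization == "pair_mean":
            cv = _group_cv(v)
        elif normalization == "view_mean":
            # normalized later by the view-level mean; store |diff| (n=2) or sd
            cv = abs(v[0] - v[1]) if len(v) == 2 else float(v.std(ddof=1))
        else:
            raise ValueError("normalization must be 'pair_mean' or 'view_mean'")
        rows.append({"turtle_id": tid, "view": view, "measure": meas, "cv": cv})
    per_group = pd.DataFrame(rows)
    if per_group.empty:
        raise ValueError("no (turtle, view) group has >= 2 replicates")
    if normalization == "view_mean":
        view_means = (
            table.groupby(["view", "measure"])["value"].mean().rename("vm").reset_index()
        )
        per_group = per_group.merge(view_means, on=["view", "measure"])
        per_group["cv"] = per_group["cv"] / per_group["vm"]
        per_group = per_group.drop(columns="vm")
    per_view = (
        per_group.groupby(["measure", "view"])["cv"].mean().rename("within_cv").reset_index()
    )
    per_measure = (
        per_view.groupby("measure")["within_cv"]
        .agg(within_cv="mean", within_cv_sd_views="std")
        .reset_index()
    )
    return per_view, per_measure


def across_individual_cv(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-individual CV: per (measure, view), each turtle contributes
    its replicate mean, and the CV = sd/mean is taken across turtles; the
    per-measure value averages over views."""
    table = _validate_table(table)
    turtle_means = (
        table.groupby(["measure", "view", "turtle_id"])["value"].mean().reset_index()
    )
    rows = []
    for (meas, view), grp in turtle_means.groupby(["measure", "view"]):
        cv = cv_standard(grp["value"].to_numpy())
        rows.append({"measure": meas, "view": view, "across_cv": cv})
    per_view = pd.DataFrame(rows)
    per_measure = (
        per_view.groupby("measure")["across_cv"]
        .agg(across_cv="mean", across_cv_sd_views="std")
        .reset_index()
    )
    return per_view, per_measure


def noise_ratio(
    within_per_measure: pd.DataFrame,
    across_per_measure: pd.DataFrame,
    flag_threshold: float = SUBSTANTIAL_CV,
) -> pd.DataFrame:
    """Within/across CV ratio per measure — the fraction of the observed
    between-individual variability attributable to measurement noise.
    Ratios above ``flag_threshold`` are flagged."""
    merged = within_per_measure.merge(across_per_measure, on="measure")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = merged["within_cv"] / merged["across_cv"]
    ratio = ratio.where(merged["across_cv"] > 0)
    merged["noise_ratio"] = ratio
    merged["substantial"] = merged["noise_ratio"] > flag_threshold
    return merged[["measure", "within_cv", "across_cv", "noise_ratio", "substantial"]]


def threshold_sensitivity(
    items,
    taus=DEFAULT_SENSITIVITY_TAUS,
    baseline: float = DEFAULT_BASELINE_TAU,
    config: ExtractionConfig | None = None,
) -> pd.DataFrame:
    """Sensitivity of fractional area to the yellowness threshold.

    ``items`` is a sequence of (image, mask) pairs (each image carries its
    view in metadata). For every view and test threshold the table reports
    the mean FA, its percent change relative to the baseline threshold, and
    the mean pairwise CV between baseline and test FA per image.
    """
    cfg = config or ExtractionConfig()
    records = []
    for image, mask in items:
        fa = {}
        for tau in {baseline, *taus}:
            pat = extract_pattern(image, mask, dataclasses.replace(cfg, tau=tau))
            fa[tau] = fractional_area(pat, mask)
        records.append({"view": image.meta.view, **{f"fa_{t}": fa[t] for t in fa}})
    df = pd.DataFrame(records)
    rows = []
    for view, grp in df.groupby("view"):
        base_vals = grp[f"fa_{baseline}"].to_numpy()
        base_mean = base_vals.mean()
        for tau in taus:
            vals = grp[f"fa_{tau}"].to_numpy()
            pct = (
                float("nan")
                if base_mean == 0
                else (vals.mean() - base_mean) / base_mean * 100.0
            )
            cvs = [cv_pairwise(b, t) for b, t in zip(base_vals, vals)]
            rows.append(
                {
                    "view": view,
                    "tau": tau,
                    "baseline": baseline,
                    "mean_fa": vals.mean(),
                    "mean_fa_baseline": base_mean,
                    "pct_change": pct,
                    "cv": float(np.nanmean(cvs)) if cvs else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def _two_sided_f_p(f_stat: float, df1: int, df2: int) -> float:
    p_one = stats.f.sf(f_stat, df1, df2)
    return float(min(1.0, 2.0 * min(p_one, 1.0 - p_one)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def group_comparison(
    table: pd.DataFrame,
    group_key: str = "source",
    welch: bool = True,
    cv_test: str = "group_standardized",
) -> pd.DataFrame:
    """Two-group comparison per (measure, view) with BH adjustment.

    Three test families: a t test on means (Welch by default), a
    variance-ratio F test (two-sided), and a CV-difference test — by default
    an F test on values standardized by their group means (so each group's
    variance becomes its squared CV), optionally the Feltz–Miller asymptotic
    CV test (``cv_test="feltz_miller"``). Within each family, p-values are
    BH-adjusted across measures per view. Each turtle contributes its
    replicate mean.
    """
    table = _validate_table(table)
    if group_key not in table.columns:
        raise ValueError(f"missing group column {group_key!r}")
    groups = sorted(table[group_key].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups in {group_key!r}, got {groups}")
    g1, g2 = groups
    turtle_means = (
        table.groupby(["measure", "view", group_key, "turtle_id"])["value"]
        .mean()
        .reset_index()
    )
    rows = []
    for (meas, view), grp in turtle_means.groupby(["measure", "view"]):
        x = grp.loc[grp[group_key] == g1, "value"].to_numpy(dtype=float)
        y = grp.loc[grp[group_key] == g2, "value"].to_numpy(dtype=float)
        x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if len(x) < 2 or len(y) < 2 or (x.std() == 0 and y.std() == 0):
            logger.info("skipping %s/%s: degenerate group", meas, view)
            continue
        t_stat, t_p = stats.ttest_ind(x, y, equal_var=not welch)
        f_stat = x.var(ddof=1) / y.var(ddof=1) if y.var(ddof=1) > 0 else np.inf
        f_p = _two_sided_f_p(f_stat, len(x) - 1, len(y) - 1)
        cv_stat, cv_p = _cv_difference_test(x, y, cv_test)
        rows.append(
            {
                "measure": meas,
                "view": view,
                "group1": g1,
                "group2": g2,
                "n1": len(x),
                "n2": len(y),
                "t_stat": float(t_stat),
                "t_p": float(t_p),
                "f_stat": float(f_stat),
                "f_p": f_p,
                "cv_stat": cv_stat,
                "cv_p": cv_p,
                "cv_test": cv_test,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    for fam in ("t_p", "f_p", "cv_p"):
        out[fam.replace("_p", "_p_adj")] = np.nan
        for view in out["view"].unique():
            sel = out["view"] == view
            out.loc[sel, fam.replace("_p", "_p_adj")] = bh_adjust(out.loc[sel, fam])
    return out


def _cv_difference_test(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "group_standardized":
        mx, my = x.mean(), y.mean()
        if mx == 0 or my == 0:
            return float("nan"), float("nan")
        xs, ys = x / mx, y / my  # variance of xs is CV(x)^2
        vx, vy = xs.var(ddof=1), ys.var(ddof=1)
        if vy == 0:
            return float("inf"), 0.0
        f_stat = vx / vy
        return float(f_stat), _two_sided_f_p(f_stat, len(x) - 1, len(y) - 1)
    if method == "feltz_miller":
        # Feltz & Miller (1996) asymptotic chi-square test for k=2 CVs
        cvs = np.array([cv_standard(x), cv_standard(y)])
        if not np.isfinite(cvs).all():
            return float("nan"), float("nan")
        m = np.array([len(x) - 1, len(y) - 1], dtype=float)
        pooled = (m * cvs).sum() / m.sum()
        denom = pooled**2 * (0.5 + pooled**2)
        if denom == 0:
            return float("nan"), float("nan")
        d_ad = (m * (cvs - pooled) ** 2).sum() / denom
        return float(d_ad), float(stats.chi2.sf(d_ad, df=1))
    raise ValueError("cv_test must be 'group_standardized' or 'feltz_miller'")
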