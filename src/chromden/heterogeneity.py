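"""Single-cell expression-heterogeneity cascade.

Counts are CPM-normalized per cell; per-gene mean and CV (sd/mean across
cells) are computed; genes are discretized into logarithmically spaced
mean-expression intervals so that variability can be compared among
peers of similar mean (the technical CV of scRNA-seq falls with mean
expression, confounding raw CV comparisons); within each interval, genes
whose CV exceeds the interval mean by 3 interval standard deviations are
flagged as highly variable; genes whose mean expression differs between
conditions are removed by a rank-sum test with Benjamini-Hochberg
q-values (retain q > 0.01); and a bimodality census counts genes whose
expression distribution rejects unimodality by Hartigan's dip test
(p < 0.01) in each condition.  The census runs on all shared genes
without the high-CV filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dip import DEFAULT_NULL_REPLICATES, dip_test
from .exceptions import InsufficientDataError, InvalidSpecError

__all__ = [
    "cpm_normalize",
    "gene_stats",
    "log_interval_binning",
    "highcv_filter",
    "interval_cv_zscore",
    "equal_mean_filter",
    "dip_test",
    "bimodality_census",
    "heterogeneity_table",
    "N_INTERVALS",
    "HIGHCV_Z",
]

#: number of logarithmically spaced mean-expression intervals
N_INTERVALS = 50

#: z threshold of the within-interval high-CV rule
HIGHCV_Z = 3.0


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per cell: each column is scaled to sum to 1e6."""
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise InvalidSpecError(f"duplicate gene id {dup!r}")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise InvalidSpecError(f"cell {zero.index[0]!r} has zero total count")
    return counts * (1e6 / totals)


def gene_stats(cpm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean and CV (sample sd / mean) of CPM across cells.

    Genes with zero mean get CV = NaN and are excluded downstream.
    """
    if cpm.shape[1] < 2:
        raise InsufficientDataError(f"need >= 2 cells, got {cpm.shape[1]}")
    mean = cpm.mean(axis=1)
    sd = cpm.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame({"mean": mean, "cv": cv}, index=cpm.index)


def log_interval_binning(means: pd.Series, n_intervals: int = N_INTERVALS) -> pd.Series:
    """Assign positive means to logarithmically spaced intervals.

    Boundaries span [min, max] of the positive means; intervals are
    half-open [lo, hi) with the last interval closed, so every positive
    mean lands in exactly one interval.  Returns a nullable-integer
    series (NA for non-positive means).
    """
    if n_intervals < 2:
        raise ValueError(f"n_intervals must be >= 2, got {n_intervals}")
    means = pd.Series(means)
    out = pd.Series(pd.NA, index=means.index, dtype="Int64")
    pos = means[means > 0]
    if pos.empty:
        return out
    lo, hi = float(pos.min()), float(pos.max())
    if lo == hi:
        out.loc[pos.index] = 0
        return out
    bounds = np.geomspace(lo, hi, n_intervals + 1)
    idx = np.searchsorted(bounds[1:-1], pos.to_numpy(), side="right")
    out.loc[pos.index] = idx
    return out


def highcv_filter(
    table: pd.DataFrame, z_threshold: float = HIGHCV_Z, literal_3sd: bool = False
) -> pd.DataFrame:
    """Flag genes whose CV is extreme among interval peers.

    Within each interval, a gene is flagged when its CV exceeds the
    interval mean CV by `z_threshold` interval standard deviations; with
    ``literal_3sd`` the alternative literal reading (CV > 3 * interval
    sd) is applied instead.  Intervals with fewer than 3 genes flag
    nothing.  Adds a boolean ``highcv`` column.
    """
    if "interval" not in table or "cv" not in table:
        raise ValueError("table needs 'interval' and 'cv' columns")
    flags = pd.Series(False, index=table.index)
    valid = table["interval"].notna() & table["cv"].notna()
    for _, grp in table[valid].groupby("interval"):
        if len(grp) < 3:
            continue
        sd = grp["cv"].std(ddof=1)
        if sd == 0:
            continue
        if literal_3sd:
            cut = z_threshold * sd
        else:
            cut = grp["cv"].mean() + z_threshold * sd
        flags.loc[grp.index[grp["cv"] > cut]] = True
    out = table.copy()
    out["highcv"] = flags
    return out


def interval_cv_zscore(table: pd.DataFrame) -> pd.Series:
    """CV z-scored within its mean-expression interval (removes the
    mean-to-CV technical trend; intervals with < 3 genes get NaN)."""
    z = pd.Series(np.nan, index=table.index)
    valid = table["interval"].notna() & table["cv"].notna()
    for _, grp in table[valid].groupby("interval"):
        if len(grp) < 3:
            continue
        sd = grp["cv"].std(ddof=1)
        if sd == 0:
            continue
        z.loc[grp.index] = (grp["cv"] - grp["cv"].mean()) / sd
    return z


def equal_mean_filter(
    cpm_a: pd.DataFrame, cpm_b: pd.DataFrame, q_threshold: float = 0.01
) -> pd.DataFrame:
    """Retain genes whose mean expression is statistically indistinguishable.

    Per shared gene, a two-sided Wilcoxon rank-sum test on CPM across
    cells; Benjamini-Hochberg q-values; genes with q > `q_threshold` are
    retained.  Returns a DataFrame with p, q and a boolean ``retained``.
    """
    shared = cpm_a.index.intersection(cpm_b.index)
    if shared.empty:
        raise InvalidSpecError("no shared genes between conditions")
    a = cpm_a.loc[shared].to_numpy()
    b = cpm_b.loc[shared].to_numpy()
    pvals = np.empty(len(shared))
    for i in range(len(shared)):
        if np.ptp(a[i]) == 0 and np.ptp(b[i]) == 0 and a[i][0] == b[i][0]:
            pvals[i] = 1.0
        else:
            pvals[i] = stats.mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"p": pvals, "q": qvals, "retained": qvals > q_threshold}, index=shared
    )


def bimodality_census(
    cpm_a: pd.DataFrame,
    cpm_b: pd.DataFrame,
    p_threshold: float = 0.01,
    n_replicates: int = DEFAULT_NULL_REPLICATES,
) -> dict:
    """Dip-test bimodality census over all shared genes.

    Returns a dict with per-condition bimodal counts, the percent change
    from a to b, the genes switching unimodal->bimodal, retention
    violations (bimodal in a but not in b), and the per-gene table.
    """
    shared = cpm_a.index.intersection(cpm_b.index)
    if shared.empty:
        raise InvalidSpecError("no shared genes between conditions")
    recs = {}
    for cond, cpm in (("a", cpm_a), ("b", cpm_b)):
        ps = np.empty(len(shared))
        for i, g in enumerate(shared):
            ps[i] = dip_test(cpm.loc[g].to_numpy(), n_replicates=n_replicates)[1]
        recs[f"dip_p_{cond}"] = ps
    table = pd.DataFrame(recs, index=shared)
    table["bimodal_a"] = table["dip_p_a"] < p_threshold
    table["bimodal_b"] = table["dip_p_b"] < p_threshold
    n_a = int(table["bimodal_a"].sum())
    n_b = int(table["bimodal_b"].sum())
    switchers = table.index[~table["bimodal_a"] & table["bimodal_b"]].tolist()
    violations = table.index[table["bimodal_a"] & ~table["bimodal_b"]].tolist()
    percent = 100.0 * (n_b - n_a) / n_a if n_a > 0 else np.nan
    return {
        "n_bimodal_a": n_a,
        "n_bimodal_b": n_b,
        "percent_change": percent,
        "switchers": switchers,
        "retention_violations": violations,
        "table": table,
    }


def heterogeneity_table(
    counts: pd.DataFrame,
    n_intervals: int = N_INTERVALS,
    z_threshold: float = HIGHCV_Z,
    dip: bool = False,
    n_replicates: int = DEFAULT_NULL_REPLICATES,
) -> pd.DataFrame:
    """One-stop per-gene heterogeneity table for one condition.

    CPM-normalizes, computes mean/CV, assigns log intervals, flags
    high-CV genes; optionally adds dip-test p-values per gene.
    """
    cpm = cpm_normalize(counts)
    table = gene_stats(cpm)
    table["interval"] = log_interval_binning(table["mean"], n_intervals)
    table = highcv_filter(table, z_threshold)
    if dip:
        ps = np.full(len(table), np.nan)
        for i, g in enumerate(table.index):
            vals = cpm.loc[g].to_numpy()
            if vals.size >= 4:
                ps[i] = dip_test(vals, n_replicates=n_replicates)[1]
        table["dip_p"] = ps
        table["bimodal"] = table["dip_p"] < 0.01
    return table
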