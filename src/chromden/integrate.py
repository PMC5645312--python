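"""Joint density-heterogeneity analyses.

Differentiation arrows place each gene at (Gamma, CV) coordinates in two
conditions; the arrow points from the stem state to the differentiated
state, and its quadrant records the sign pair (delta Gamma, delta CV).
Quartile comparisons contrast the density of high-CV versus low-CV genes
with bootstrap confidence intervals, and hierarchical clustering groups
genes by their density profile across three or more conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .exceptions import ConfigurationError, InsufficientDataError, InvalidSpecError

__all__ = [
    "build_arrows",
    "quadrant_fractions",
    "density_by_cv_class",
    "QuartileComparison",
    "cluster_density_changes",
]


def build_arrows(
    density: pd.DataFrame,
    het_a: pd.DataFrame,
    het_b: pd.DataFrame,
    cond_a: str = "a",
    cond_b: str = "b",
    gene_filter=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One differentiation arrow per gene present in all inputs.

    density : table with gene_id and gamma_<cond_a>, gamma_<cond_b>.
    het_a, het_b : per-gene tables (indexed by gene id) with a 'cv' column.
    gene_filter : optional iterable restricting the join.

    Returns (arrows, missing): genes lacking any coordinate are reported
    in `missing` with the coordinate they lack, never silently dropped.
    Quadrants: '++' density up & CV up, '+-' density up & CV down, etc.;
    arrows with a zero component are labelled 'tie'.
    """
    ga, gb = f"gamma_{cond_a}", f"gamma_{cond_b}"
    for col in (ga, gb):
        if col not in density:
            raise ConfigurationError(f"density table lacks {col!r}")
    dens = density.set_index("gene_id") if "gene_id" in density else density
    genes = dens.index
    if gene_filter is not None:
        genes = genes.intersection(pd.Index(gene_filter))
    rows, missing = [], []
    for g in genes:
        cv_a = het_a["cv"].get(g, np.nan)
        cv_b = het_b["cv"].get(g, np.nan)
        if pd.isna(cv_a) or pd.isna(cv_b):
            which = "cv_a" if pd.isna(cv_a) else "cv_b"
            missing.append({"gene_id": g, "missing": which})
            continue
        gam_a, gam_b = float(dens.at[g, ga]), float(dens.at[g, gb])
        d_gamma, d_cv = gam_b - gam_a, cv_b - cv_a
        if d_gamma == 0 or d_cv == 0:
            quadrant = "tie"
        else:
            quadrant = ("+" if d_gamma > 0 else "-") + ("+" if d_cv > 0 else "-")
        rows.append(
            {
                "gene_id": g,
                "gamma_a": gam_a,
                "gamma_b": gam_b,
                "cv_a": float(cv_a),
                "cv_b": float(cv_b),
                "d_gamma": d_gamma,
                "d_cv": float(d_cv),
                "quadrant": quadrant,
            }
        )
    if not rows and not missing:
        raise InvalidSpecError("empty join: no genes shared by density and CV tables")
    arrows = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "gamma_a",
            "gamma_b",
            "cv_a",
            "cv_b",
            "d_gamma",
            "d_cv",
            "quadrant",
        ],
    )
    return arrows, pd.DataFrame(missing, columns=["gene_id", "missing"])


def quadrant_fractions(arrows: pd.DataFrame) -> dict:
    """Fractions of non-tie arrows per quadrant (they sum to 1), plus the
    tie count reported separately."""
    if len(arrows) == 0:
        raise InsufficientDataError("no arrows")
    ties = int((arrows["quadrant"] == "tie").sum())
    real = arrows[arrows["quadrant"] != "tie"]
    fractions = {}
    if len(real):
        counts = real["quadrant"].value_counts()
        fractions = {q: float(c) / len(real) for q, c in counts.items()}
    return {"fractions": fractions, "n_arrows": int(len(real)), "n_ties": ties}


@dataclass
class QuartileComparison:
    """Gamma quartiles of high- vs low-CV genes with bootstrap CIs."""

    quartiles_high: np.ndarray
    quartiles_low: np.ndarray
    ci_high: np.ndarray  # (2, 3): lower/upper CI per quartile
    ci_low: np.ndarray
    p_value: float
    n_high: int
    n_low: int


def density_by_cv_class(
    density: pd.DataFrame,
    het: pd.DataFrame,
    cond: str = "a",
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> QuartileComparison:
    """Compare Gamma between high-CV and low-CV genes.

    het must carry a boolean 'highcv' column (within-interval z-rule).
    Quartiles (Q1, Q2, Q3) of Gamma per class with seeded bootstrap
    percentile CIs and a two-sided rank-sum p-value.
    """
    gcol = f"gamma_{cond}"
    if gcol not in density:
        raise ConfigurationError(f"density table lacks {gcol!r}")
    dens = density.set_index("gene_id") if "gene_id" in density else density
    shared = dens.index.intersection(het.index[het["cv"].notna()])
    gam = dens.loc[shared, gcol].to_numpy(dtype=float)
    flags = het.loc[shared, "highcv"].to_numpy(dtype=bool)
    hi, lo = gam[flags], gam[~flags]
    for name, arr in (("high-CV", hi), ("low-CV", lo)):
        if arr.size == 0:
            raise InsufficientDataError(f"empty {name} class")
    q = (25, 50, 75)
    rng = np.random.default_rng(seed)

    def boot(arr):
        reps = np.empty((n_boot, 3))
        for i in range(n_boot):
            reps[i] = np.percentile(rng.choice(arr, arr.size, replace=True), q)
        alpha = (1 - ci) / 2
        return np.percentile(reps, [100 * alpha, 100 * (1 - alpha)], axis=0)

    p = float(stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue)
    return QuartileComparison(
        quartiles_high=np.percentile(hi, q),
        quartiles_low=np.percentile(lo, q),
        ci_high=boot(hi),
        ci_low=boot(lo),
        p_value=p,
        n_high=int(hi.size),
        n_low=int(lo.size),
    )


def cluster_density_changes(
    density: pd.DataFrame,
    conditions: list[str],
    de_exclusion: set | None = None,
    n_clusters: int = 2,
) -> tuple[pd.Series, np.ndarray]:
    """Ward hierarchical clustering of per-gene standardized Gamma profiles.

    Differentially expressed genes (externally supplied list) are removed
    first.  Returns (cluster labels indexed by gene, scipy linkage
    matrix); clustering is deterministic.
    """
    if len(conditions) < 2:
        raise ConfigurationError("need >= 2 conditions to cluster profiles")
    cols = [f"gamma_{c}" for c in conditions]
    for col in cols:
        if col not in density:
            raise ConfigurationError(f"density table lacks {col!r}")
    dens = density.set_index("gene_id") if "gene_id" in density else density
    if de_exclusion:
        dens = dens.loc[~dens.index.isin(set(de_exclusion))]
    if len(dens) < 2:
        raise InsufficientDataError(f"only {len(dens)} genes after DE exclusion")
    profiles = dens[cols].to_numpy(dtype=float)
    mu = profiles.mean(axis=1, keepdims=True)
    sd = profiles.std(axis=1, keepdims=True)
    # regularized standardization: a plain z-score turns flat profiles into
    # amplified noise; the ridge keeps no-change genes near the origin
    z = (profiles - mu) / (sd + 0.05 * np.abs(mu) + 1e-12)
    link = hierarchy.linkage(z, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=dens.index, name="cluster"), link
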