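"""Synthetic Hi-C matrices, gene annotations and single-cell count matrices
with planted ground truth.

The polymer generator emulates the distance-decay contact structure of a
chromosome arm: pair distances grow as |i - j|**nu in bin units and the
interaction frequency is their reciprocal, so with distance exponent e = 1
the model distance recovered downstream equals the generated one.
Condensation hotspots shrink within-block distances by a compaction
factor before inversion, which guarantees the local density Gamma can
only increase there.

The count generator emulates droplet-style expression matrices: gene
means follow a log-normal law, counts are negative binomial (Poisson
sampling noise plus a dispersion floor reproduces the decreasing
mean-to-CV technical trend), planted high-variability genes get an
inflated dispersion at unchanged mean in the second condition, and
planted bimodal genes are two-component negative-binomial mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecError
from .hic import DEFAULT_RESOLUTION_BP, InteractionMatrix

__all__ = [
    "PolymerModelSpec",
    "CountsModelSpec",
    "gen_unfolded_polymer_matrix",
    "gen_condensing_pair",
    "gen_gene_annotation",
    "gen_counts",
    "write_interaction_matrix",
    "write_gene_annotation",
    "write_counts_tsv",
    "write_counts_mtx",
]


@dataclass
class PolymerModelSpec:
    """Distance-decay polymer with condensation hotspots.

    hotspot_blocks : list of (start_bin, end_bin, compaction_factor);
        half-open bin ranges, factor in (0, 1] multiplies within-block
        distances in the post-condensation state.
    decay_exponent : nu in d_ij = |i - j|**nu.  The default 1 gives the
        fractal-globule-like contact decay IF ~ 1/s.
    """

    n_bins: int
    decay_exponent: float = 1.0
    hotspot_blocks: list[tuple[int, int, float]] = field(default_factory=list)
    chromosome: str = "chrS"
    resolution_bp: int = DEFAULT_RESOLUTION_BP
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 3:
            raise InvalidSpecError(f"n_bins must be >= 3, got {self.n_bins}")
        if self.decay_exponent <= 0:
            raise InvalidSpecError("decay_exponent must be positive")
        spans = []
        for start, end, factor in self.hotspot_blocks:
            if not (0 <= start < end <= self.n_bins):
                raise InvalidSpecError(
                    f"hotspot block [{start}, {end}) outside [0, {self.n_bins})"
                )
            if not (0 < factor <= 1):
                raise InvalidSpecError(f"compaction factor {factor} outside (0, 1]")
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise InvalidSpecError(
                    f"hotspot blocks overlap: [{s1}, {e1}) and [{s2}, {e2})"
                )

    @property
    def hotspot_bins(self) -> set[int]:
        bins: set[int] = set()
        for start, end, _ in self.hotspot_blocks:
            bins.update(range(start, end))
        return bins


def gen_unfolded_polymer_matrix(
    n_bins: int, chromosome: str = "chrU", resolution_bp: int = DEFAULT_RESOLUTION_BP
) -> InteractionMatrix:
    """Contact matrix of an unfolded polymer: IF_ij = 1/|i - j|, zero
    diagonal.  With e = 1 the model distance equals genomic separation in
    bins, so c(R) of a central locus falls off as 1/R^2."""
    if n_bins < 3:
        raise InvalidSpecError(f"n_bins must be >= 3, got {n_bins}")
    idx = np.arange(n_bins)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        mat = np.where(sep > 0, 1.0 / sep, 0.0)
    return InteractionMatrix(mat, chromosome=chromosome, resolution_bp=resolution_bp)


def _distance_matrix(spec: PolymerModelSpec, condensed: bool) -> np.ndarray:
    idx = np.arange(spec.n_bins)
    sep = np.abs(idx[:, None] - idx[None, :]).astype(float)
    dist = sep**spec.decay_exponent
    if condensed:
        for start, end, factor in spec.hotspot_blocks:
            block = slice(start, end)
            dist[block, block] = dist[block, block] * factor
    return dist


def gen_condensing_pair(
    spec: PolymerModelSpec,
) -> tuple[InteractionMatrix, InteractionMatrix, set[int]]:
    """Pre/post-condensation matrix pair plus the planted hotspot bin set.

    Post equals pre except that distances between bin pairs inside the
    same hotspot block are multiplied by the block's compaction factor
    before inversion to interaction frequencies; density at hotspot bins
    is therefore monotonically non-decreasing by construction.
    """
    mats = []
    for condensed in (False, True):
        dist = _distance_matrix(spec, condensed)
        with np.errstate(divide="ignore"):
            mat = np.where(dist > 0, 1.0 / dist, 0.0)
        np.fill_diagonal(mat, 0.0)
        mats.append(
            InteractionMatrix(mat, chromosome=spec.chromosome, resolution_bp=spec.resolution_bp)
        )
    return mats[0], mats[1], spec.hotspot_bins


def gen_gene_annotation(
    n_genes: int,
    n_bins: int,
    resolution_bp: int = DEFAULT_RESOLUTION_BP,
    strand_fraction: float = 0.5,
    chromosome: str = "chrS",
    gene_length_bp: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Non-overlapping gene intervals with randomized strands.

    Genes are placed one per equal-width slot with jitter, which keeps
    placement deterministic under the seed and guarantees no overlap.
    """
    if n_genes < 0:
        raise InvalidSpecError("n_genes must be non-negative")
    if not (0.0 <= strand_fraction <= 1.0):
        raise InvalidSpecError("strand_fraction must be in [0, 1]")
    genome_bp = n_bins * resolution_bp
    if gene_length_bp is None:
        gene_length_bp = max(resolution_bp // 2, 1)
    if n_genes > 0 and n_genes * gene_length_bp > genome_bp:
        raise InvalidSpecError(
            f"cannot pack {n_genes} genes of {gene_length_bp} bp into {genome_bp} bp"
        )
    rng = np.random.default_rng(seed)
    rows = []
    if n_genes > 0:
        slot = genome_bp // n_genes
        for g in range(n_genes):
            jitter_room = slot - gene_length_bp
            start = g * slot + (int(rng.integers(0, jitter_room + 1)) if jitter_room > 0 else 0)
            strand = "+" if rng.random() < strand_fraction else "-"
            rows.append(
                {
                    "gene_id": f"gene{g:05d}",
                    "chromosome": chromosome,
                    "start": start,
                    "end": start + gene_length_bp,
                    "strand": strand,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])


@dataclass
class CountsModelSpec:
    """Two-condition single-cell count model with planted structure.

    mean_law : (log10_mean, log10_sd) of the gene-mean distribution.
    dispersion_phi : squared biological CV floor added to Poisson noise
        (negative binomial with 1/size = phi).
    highcv_phi_boost : multiplier on phi for planted high-CV genes in
        condition b (their configured means are unchanged).
    planted_bimodal : {gene_index: {"a": (low_mean, high_mean, mix) or None,
        "b": ...}}; None leaves the gene unimodal in that condition.
    cell_size_log_sd : sigma of the log-normal per-cell size factors
        (capture-efficiency variation); realistic library-size spread is
        what keeps CPM values of low-count genes off the integer lattice.
    """

    n_genes: int
    n_cells_a: int
    n_cells_b: int
    mean_law: tuple[float, float] = (1.7, 0.6)
    dispersion_phi: float = 0.05
    planted_highcv_genes: frozenset[int] = frozenset()
    highcv_phi_boost: float = 10.0
    planted_bimodal: dict[int, dict] = field(default_factory=dict)
    cell_size_log_sd: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_cells_a, self.n_cells_b) < 1:
            raise InvalidSpecError("n_genes and cell counts must be positive")
        if self.dispersion_phi < 0:
            raise InvalidSpecError("dispersion_phi must be non-negative")
        if self.highcv_phi_boost <= 1:
            raise InvalidSpecError("highcv_phi_boost must exceed 1")
        self.planted_highcv_genes = frozenset(self.planted_highcv_genes)
        overlap = self.planted_highcv_genes & set(self.planted_bimodal)
        if overlap:
            raise InvalidSpecError(
                f"planted high-CV and bimodal sets overlap: {sorted(overlap)[:5]}"
            )
        all_planted = self.planted_highcv_genes | set(self.planted_bimodal)
        bad = [g for g in all_planted if not (0 <= g < self.n_genes)]
        if bad:
            raise InvalidSpecError(f"planted gene indices out of range: {bad[:5]}")


def _nb_draw(rng: np.random.Generator, mean, phi: float, size: int) -> np.ndarray:
    """Negative binomial with mean `mean` (scalar or per-cell vector) and
    variance mean + phi * mean^2."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    if phi <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gen_counts(
    spec: CountsModelSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (counts_a, counts_b, truth) for the two conditions.

    counts are genes x cells integer DataFrames; truth labels each gene
    as 'null', 'highcv', or 'bimodal' with per-condition bimodality
    flags.
    """
    rng = np.random.default_rng(spec.seed)
    log10_mu, log10_sd = spec.mean_law
    zs = rng.normal(0.0, 1.0, spec.n_genes)
    planted_any = spec.planted_highcv_genes | set(spec.planted_bimodal)
    if planted_any:
        # keep planted genes spread over the well-populated central mean
        # range so their interval has enough peers for the 3-sd rule to
        # see them (and no two share an atom at a range boundary)
        idx = np.sort(np.fromiter(planted_any, dtype=np.int64))
        zs[idx] = rng.uniform(-1.0, 1.0, idx.size)
    means = 10.0 ** (log10_mu + log10_sd * zs)
    gene_ids = [f"gene{g:05d}" for g in range(spec.n_genes)]
    out = {}
    for cond, n_cells in (("a", spec.n_cells_a), ("b", spec.n_cells_b)):
        counts = np.empty((spec.n_genes, n_cells), dtype=np.int64)
        size_factors = rng.lognormal(0.0, spec.cell_size_log_sd, n_cells)
        for g in range(spec.n_genes):
            mixture = spec.planted_bimodal.get(g, {}).get(cond) if g in spec.planted_bimodal else None
            if mixture is not None:
                low, high, mix = mixture
                comp = rng.random(n_cells) < mix
                vals = np.where(
                    comp,
                    _nb_draw(rng, high * size_factors, spec.dispersion_phi, n_cells),
                    _nb_draw(rng, low * size_factors, spec.dispersion_phi, n_cells),
                )
                counts[g] = vals
            else:
                phi = spec.dispersion_phi
                if cond == "b" and g in spec.planted_highcv_genes:
                    phi = phi * spec.highcv_phi_boost
                counts[g] = _nb_draw(rng, means[g] * size_factors, phi, n_cells)
        out[cond] = pd.DataFrame(
            counts,
            index=pd.Index(gene_ids, name="gene_id"),
            columns=[f"cell_{cond}{c:04d}" for c in range(n_cells)],
        )
    labels = []
    for g in range(spec.n_genes):
        if g in spec.planted_highcv_genes:
            label = "highcv"
        elif g in spec.planted_bimodal:
            label = "bimodal"
        else:
            label = "null"
        bim = spec.planted_bimodal.get(g, {})
        labels.append(
            {
                "gene_id": gene_ids[g],
                "label": label,
                "configured_mean": means[g],
                "bimodal_a": bool(bim.get("a")),
                "bimodal_b": bool(bim.get("b")),
            }
        )
    truth = pd.DataFrame(labels).set_index("gene_id")
    return out["a"], out["b"], truth


# ---------------------------------------------------------------- writers


def write_interaction_matrix(matrix: InteractionMatrix, path, dialect: str = "dense") -> None:
    """Write a contact matrix as dense whitespace text (with a .bins BED
    sidecar) or as sparse upper-triangle triplets."""
    if dialect == "dense":
        np.savetxt(path, matrix.values, fmt="%.8g", delimiter="\t")
        with open(str(path) + ".bins", "w") as fh:
            for i, start in enumerate(matrix.bin_start_coords):
                fh.write(
                    f"{matrix.chromosome}\t{start}\t{start + matrix.resolution_bp}\tbin{i}\n"
                )
    elif dialect == "sparse":
        with open(path, "w") as fh:
            n = matrix.n_bins
            for i in range(n):
                for j in range(i, n):
                    v = matrix.values[i, j]
                    if v != 0:
                        fh.write(f"{i}\t{j}\t{v:.8g}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def write_gene_annotation(annotation: pd.DataFrame, path) -> None:
    """6-column BED (0-based half-open; score column unused)."""
    with open(path, "w") as fh:
        for _, g in annotation.iterrows():
            fh.write(
                f"{g['chromosome']}\t{g['start']}\t{g['end']}\t{g['gene_id']}\t0\t{g['strand']}\n"
            )


def read_gene_annotation(path) -> pd.DataFrame:
    """Read a 6-column BED gene annotation."""
    from .exceptions import FormatError

    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) < 6:
                raise FormatError(f"expected >= 6 BED columns, got {len(toks)}", path, ln)
            if toks[5] not in ("+", "-"):
                raise FormatError(f"bad strand {toks[5]!r}", path, ln)
            rows.append(
                {
                    "gene_id": toks[3],
                    "chromosome": toks[0],
                    "start": int(toks[1]),
                    "end": int(toks[2]),
                    "strand": toks[5],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end", "strand"])


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_counts_mtx(counts: pd.DataFrame, path_prefix: str) -> None:
    """MatrixMarket triplet file plus .rows/.cols name sidecars."""
    from scipy import io as sio
    from scipy import sparse

    sio.mmwrite(f"{path_prefix}.mtx", sparse.coo_matrix(counts.to_numpy()))
    with open(f"{path_prefix}.rows", "w") as fh:
        fh.write("\n".join(map(str, counts.index)) + "\n")
    with open(f"{path_prefix}.cols", "w") as fh:
        fh.write("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(path_prefix: str) -> pd.DataFrame:
    from scipy import io as sio

    mat = sio.mmread(f"{path_prefix}.mtx").toarray().astype(np.int64)
    with open(f"{path_prefix}.rows") as fh:
        rows = fh.read().split()
    with open(f"{path_prefix}.cols") as fh:
        cols = fh.read().split()
    return pd.DataFrame(mat, index=pd.Index(rows, name="gene_id"), columns=cols)
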