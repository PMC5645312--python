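"""Declarative pipeline configuration and artifact-writing stage runners.

The pipeline has many fixed thresholds (density radius R = 2, distance
exponent e = 1, 50 log intervals, the 3-sd high-CV rule, q > 0.01
equal-mean retention, dip p < 0.01); a single config object makes them
auditable, every stage writes diff-friendly TSV/JSON artifacts with a
JSON run log (package versions, seeds, thresholds, input digests), and a
rerun with the same config and seeds reproduces outputs byte for byte.

Stages: synth (write fixtures), density (per-gene Gamma table + c(R)
profile), simulate (per-Gamma ensemble summaries), scrna (heterogeneity
tables + bimodality census), integrate (arrows, quadrant fractions,
quartile comparison, clustering).  Partial outputs are removed when a
stage fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import ConfigurationError, InsufficientDataError
from .heterogeneity import (
    HIGHCV_Z,
    N_INTERVALS,
    bimodality_census,
    cpm_normalize,
    equal_mean_filter,
    heterogeneity_table,
)
from .hic import (
    DensityParams,
    compare_density_shift,
    cumulative_radial_profile,
    density_table,
    read_interaction_matrix,
)
from .integrate import (
    build_arrows,
    cluster_density_changes,
    density_by_cv_class,
    quadrant_fractions,
)
from .synthetic import (
    CountsModelSpec,
    PolymerModelSpec,
    gen_condensing_pair,
    gen_counts,
    gen_gene_annotation,
    read_counts_tsv,
    read_gene_annotation,
    write_counts_tsv,
    write_gene_annotation,
    write_interaction_matrix,
)
from .telegraph import SweepSpec, TelegraphParams, sweep, sweep_table

__all__ = ["PipelineConfig", "run_synth", "run_density", "run_simulate",
           "run_scrna", "run_integrate", "run_all"]


@dataclass
class PipelineConfig:
    """All inputs, thresholds and seeds of a pipeline run."""

    output_dir: str = "chromden_out"
    seed: int = 0
    # input paths (filled by run_synth when fixtures are generated)
    hic_paths: dict = field(default_factory=dict)   # {condition: {chrom: path}}
    hic_dialect: str = "dense"
    annotation_path: str | None = None
    counts_paths: dict = field(default_factory=dict)  # {condition: path (TSV)}
    de_list_path: str | None = None
    # analysis parameters
    density_R: float = 2.0
    density_e: float = 1.0
    resolution_bp: int = 40_000
    n_intervals: int = N_INTERVALS
    highcv_z: float = HIGHCV_Z
    equal_mean_q: float = 0.01
    dip_p: float = 0.01
    # simulation
    sweep_gammas: list = field(default_factory=lambda: list(np.linspace(1, 99, 15)))
    n_trajectories: int = 1000
    t_end_min: float = 1000.0
    burn_in_min: float = 500.0
    # synthetic fixture knobs
    synth_n_bins: int = 800
    synth_hotspots: list = field(
        default_factory=lambda: [(120, 160, 0.5), (360, 400, 0.5), (600, 640, 0.5)]
    )
    synth_n_genes: int = 1200
    synth_n_cells: int = 300

    def __post_init__(self):
        for name in ("equal_mean_q", "dip_p"):
            val = getattr(self, name)
            if not 0.0 < val < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {val}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown config fields: {sorted(bad)}")
        return cls(**raw)

    def validate_inputs(self, stage: str) -> None:
        """Check that every path this stage needs exists; name the field."""
        missing = []
        if stage == "density":
            if not self.hic_paths:
                missing.append("hic_paths")
            for cond, by_chrom in self.hic_paths.items():
                for chrom, path in by_chrom.items():
                    if not Path(path).exists():
                        missing.append(f"hic_paths[{cond!r}][{chrom!r}] -> {path}")
            if self.annotation_path is None or not Path(self.annotation_path).exists():
                missing.append(f"annotation_path -> {self.annotation_path}")
        elif stage == "scrna":
            if not self.counts_paths:
                missing.append("counts_paths")
            for cond, path in self.counts_paths.items():
                if not Path(path).exists():
                    missing.append(f"counts_paths[{cond!r}] -> {path}")
        if missing:
            raise ConfigurationError(
                "missing or nonexistent inputs: " + "; ".join(missing)
            )

    def _thresholds(self) -> dict:
        return {
            "density_R": self.density_R,
            "density_e": self.density_e,
            "n_intervals": self.n_intervals,
            "highcv_z": self.highcv_z,
            "equal_mean_q": self.equal_mean_q,
            "dip_p": self.dip_p,
        }


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Stage:
    """Collects written artifacts; removes them if the stage fails."""

    def __init__(self, config: PipelineConfig, name: str):
        self.config = config
        self.name = name
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.written: list[Path] = []
        self.inputs: dict[str, str] = {}

    def path(self, filename: str) -> Path:
        p = self.outdir / filename
        self.written.append(p)
        return p

    def note_input(self, label: str, path) -> None:
        self.inputs[str(label)] = _digest(path)

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            for p in self.written:
                p.unlink(missing_ok=True)
            return False
        log = {
            "stage": self.name,
            "chromden_version": __version__,
            "numpy_version": np.__version__,
            "seed": self.config.seed,
            "thresholds": self.config._thresholds(),
            "input_digests": self.inputs,
            "artifacts": [p.name for p in self.written],
        }
        with open(self.outdir / f"{self.name}.log.json", "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)
        return False


def run_synth(config: PipelineConfig) -> dict:
    """Generate Hi-C/annotation/counts fixtures and point the config at
    them.  Returns {artifact: path}."""
    with _Stage(config, "synth") as st:
        poly = PolymerModelSpec(
            n_bins=config.synth_n_bins,
            hotspot_blocks=[tuple(b) for b in config.synth_hotspots],
            resolution_bp=config.resolution_bp,
            seed=config.seed,
        )
        pre, post, hotspots = gen_condensing_pair(poly)
        p_pre = st.path("hic_pre.tsv")
        p_post = st.path("hic_post.tsv")
        write_interaction_matrix(pre, p_pre, "dense")
        st.written.append(Path(str(p_pre) + ".bins"))
        write_interaction_matrix(post, p_post, "dense")
        st.written.append(Path(str(p_post) + ".bins"))
        anno = gen_gene_annotation(
            config.synth_n_genes,
            config.synth_n_bins,
            config.resolution_bp,
            chromosome=poly.chromosome,
            seed=config.seed + 1,
        )
        p_anno = st.path("genes.bed")
        write_gene_annotation(anno, p_anno)
        # planted fractions are kept small: condition-b-only mixtures add
        # counts to b's cell totals, and CPM is compositional, so heavy
        # planting would shift every null gene's CPM
        n = config.synth_n_genes
        n_highcv = max(n // 20, 1)
        n_bimodal = max(n // 40, 1)
        highcv = frozenset(range(0, n_highcv))
        bimodal = {
            g: {"a": None, "b": (5.0, 500.0, 0.5)}
            for g in range(n_highcv, n_highcv + n_bimodal)
        }
        cspec = CountsModelSpec(
            n_genes=n,
            n_cells_a=config.synth_n_cells,
            n_cells_b=config.synth_n_cells,
            planted_highcv_genes=highcv,
            planted_bimodal=bimodal,
            seed=config.seed + 2,
        )
        counts_a, counts_b, truth = gen_counts(cspec)
        p_ca, p_cb = st.path("counts_a.tsv"), st.path("counts_b.tsv")
        write_counts_tsv(counts_a, p_ca)
        write_counts_tsv(counts_b, p_cb)
        p_truth = st.path("truth.tsv")
        truth.to_csv(p_truth, sep="\t")
        hot = st.path("hotspot_bins.tsv")
        pd.Series(sorted(hotspots), name="bin").to_csv(hot, sep="\t", index=False)
        config.hic_paths = {
            "a": {poly.chromosome: str(p_pre)},
            "b": {poly.chromosome: str(p_post)},
        }
        config.annotation_path = str(p_anno)
        config.counts_paths = {"a": str(p_ca), "b": str(p_cb)}
        return {p.name: str(p) for p in st.written}


def run_density(config: PipelineConfig) -> dict:
    """Per-gene Gamma table (units: bins of resolution_bp), paired shift
    test, and the c(R) profile of the first gene's locus."""
    config.validate_inputs("density")
    with _Stage(config, "density") as st:
        matrices = {}
        for cond, by_chrom in config.hic_paths.items():
            matrices[cond] = {}
            for chrom, path in by_chrom.items():
                st.note_input(f"hic[{cond}][{chrom}]", path)
                matrices[cond][chrom] = read_interaction_matrix(
                    path, config.hic_dialect, chromosome=chrom,
                    resolution_bp=config.resolution_bp,
                )
        st.note_input("annotation", config.annotation_path)
        anno = read_gene_annotation(config.annotation_path)
        params = DensityParams(R=config.density_R, e=config.density_e)
        table, skipped = density_table(matrices, anno, params)
        conds = list(config.hic_paths)
        header = f"# gamma in bins of {config.resolution_bp} bp\n"
        p_tab = st.path("density.tsv")
        with open(p_tab, "w") as fh:
            fh.write(header)
            table.to_csv(fh, sep="\t", index=False)
        skipped.to_csv(st.path("density_skipped.tsv"), sep="\t", index=False)
        shift = {}
        if len(conds) >= 2 and len(table) >= 2:
            med, p, direction = compare_density_shift(table, conds[0], conds[1])
            shift = {"median_delta_gamma": med, "p_value": p, "direction": direction}
        with open(st.path("density_shift.json"), "w") as fh:
            json.dump(shift, fh, indent=2, sort_keys=True)
        if len(anno) and len(table):
            gene = anno.iloc[0]
            mat = matrices[conds[0]][gene["chromosome"]]
            prof = cumulative_radial_profile(
                mat, int(table.iloc[0]["tss_bin"]), e=config.density_e
            )
            prof.to_csv(st.path("radial_profile.tsv"), sep="\t", index=False)
        return {p.name: str(p) for p in st.written}


def run_simulate(config: PipelineConfig, params: TelegraphParams | None = None) -> dict:
    """Density sweep of the crowding-scaled telegraph model."""
    with _Stage(config, "simulate") as st:
        params = params or TelegraphParams()
        spec = SweepSpec(
            gamma_values=np.asarray(config.sweep_gammas, dtype=float),
            n_trajectories=config.n_trajectories,
            t_end_min=config.t_end_min,
            burn_in_min=config.burn_in_min,
            seed=config.seed,
        )
        table = sweep_table(sweep(params, spec))
        p_tab = st.path("sweep.tsv")
        with open(p_tab, "w") as fh:
            fh.write("# rates per minute; gamma in bins of 40 kb\n")
            table.to_csv(fh, sep="\t", index=False)
        return {p.name: str(p) for p in st.written}


def run_scrna(config: PipelineConfig) -> dict:
    """Heterogeneity tables per condition, equal-mean filter, census."""
    config.validate_inputs("scrna")
    with _Stage(config, "scrna") as st:
        conds = list(config.counts_paths)
        if len(conds) != 2:
            raise ConfigurationError(
                f"counts_paths must name exactly 2 conditions, got {conds}"
            )
        counts, cpm, tables = {}, {}, {}
        for cond in conds:
            st.note_input(f"counts[{cond}]", config.counts_paths[cond])
            counts[cond] = read_counts_tsv(config.counts_paths[cond])
            cpm[cond] = cpm_normalize(counts[cond])
            tables[cond] = heterogeneity_table(
                counts[cond], config.n_intervals, config.highcv_z
            )
            tables[cond].to_csv(st.path(f"heterogeneity_{cond}.tsv"), sep="\t")
        eq = equal_mean_filter(cpm[conds[0]], cpm[conds[1]], config.equal_mean_q)
        eq.to_csv(st.path("equal_mean_filter.tsv"), sep="\t")
        census = bimodality_census(cpm[conds[0]], cpm[conds[1]], config.dip_p)
        census["table"].to_csv(st.path("census_table.tsv"), sep="\t")
        summary = {k: v for k, v in census.items() if k != "table"}
        summary["percent_change"] = (
            None if pd.isna(summary["percent_change"]) else summary["percent_change"]
        )
        with open(st.path("census.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return {p.name: str(p) for p in st.written}


def run_integrate(config: PipelineConfig) -> dict:
    """Arrows, quadrant fractions, quartile comparison and clustering."""
    outdir = Path(config.output_dir)
    dens_path = outdir / "density.tsv"
    if not dens_path.exists():
        raise ConfigurationError("run_density must run before run_integrate")
    with _Stage(config, "integrate") as st:
        density = pd.read_csv(dens_path, sep="\t", comment="#")
        conds = list(config.hic_paths) or ["a", "b"]
        het = {}
        for cond in ("a", "b"):
            path = outdir / f"heterogeneity_{cond}.tsv"
            if not path.exists():
                raise ConfigurationError("run_scrna must run before run_integrate")
            het[cond] = pd.read_csv(path, sep="\t", index_col=0)
        eq_path = outdir / "equal_mean_filter.tsv"
        gene_filter = None
        if eq_path.exists():
            eq = pd.read_csv(eq_path, sep="\t", index_col=0)
            gene_filter = eq.index[eq["retained"]]
        density = density.rename(
            columns={f"gamma_{c}": f"gamma_{n}" for c, n in zip(conds, ("a", "b"))}
        )
        arrows, missing = build_arrows(density, het["a"], het["b"], gene_filter=gene_filter)
        arrows.to_csv(st.path("arrows.tsv"), sep="\t", index=False)
        missing.to_csv(st.path("arrows_missing.tsv"), sep="\t", index=False)
        with open(st.path("quadrants.json"), "w") as fh:
            json.dump(quadrant_fractions(arrows), fh, indent=2, sort_keys=True)
        try:
            qc = density_by_cv_class(density, het["a"], cond="a", seed=config.seed)
            quart = {
                "quartiles_high": qc.quartiles_high.tolist(),
                "quartiles_low": qc.quartiles_low.tolist(),
                "ci_high": qc.ci_high.tolist(),
                "ci_low": qc.ci_low.tolist(),
                "p_value": qc.p_value,
                "n_high": qc.n_high,
                "n_low": qc.n_low,
            }
        except InsufficientDataError as exc:
            quart = {"skipped": str(exc)}
        with open(st.path("quartiles.json"), "w") as fh:
            json.dump(quart, fh, indent=2, sort_keys=True)
        de = set()
        if config.de_list_path:
            de = set(Path(config.de_list_path).read_text().split())
        labels, _ = cluster_density_changes(density, ["a", "b"], de_exclusion=de)
        labels.to_csv(st.path("clusters.tsv"), sep="\t")
        return {p.name: str(p) for p in st.written}


def run_all(config: PipelineConfig) -> dict:
    """synth -> density -> scrna -> integrate (simulate is independent)."""
    artifacts = {}
    artifacts.update(run_synth(config))
    artifacts.update(run_density(config))
    artifacts.update(run_scrna(config))
    artifacts.update(run_integrate(config))
    return artifacts
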