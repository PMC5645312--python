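"""Shared fixtures: the expensive synthetic worlds are session-scoped so
generation and dip null-table calibration are paid once."""

import numpy as np
import pytest

import chromden as cd


@pytest.fixture(scope="session")
def condensing_world():
    """Polymer pair with 3 planted condensation blocks plus an annotation
    dense enough to put ~60 gene TSSs inside hotspots."""
    spec = cd.PolymerModelSpec(
        n_bins=400,
        hotspot_blocks=[(60, 80, 0.5), (180, 200, 0.5), (300, 320, 0.5)],
        seed=0,
    )
    pre, post, hotspots = cd.gen_condensing_pair(spec)
    anno = cd.gen_gene_annotation(
        400, spec.n_bins, spec.resolution_bp, chromosome=spec.chromosome, seed=1
    )
    return {"spec": spec, "pre": pre, "post": post, "hotspots": hotspots, "anno": anno}


@pytest.fixture(scope="session")
def counts_world():
    """2000-gene two-condition count world: 50 planted high-CV genes and
    29 planted bimodal genes (20 bimodal in both conditions, 9 only in b)."""
    highcv = frozenset(range(0, 50))
    bimodal = {g: {"a": (5.0, 500.0, 0.5), "b": (5.0, 500.0, 0.5)} for g in range(50, 70)}
    bimodal.update({g: {"a": None, "b": (5.0, 500.0, 0.5)} for g in range(70, 79)})
    spec = cd.CountsModelSpec(
        n_genes=2000,
        n_cells_a=300,
        n_cells_b=300,
        planted_highcv_genes=highcv,
        planted_bimodal=bimodal,
        seed=5,
    )
    counts_a, counts_b, truth = cd.gen_counts(spec)
    return {"spec": spec, "a": counts_a, "b": counts_b, "truth": truth}


@pytest.fixture(scope="session")
def census_world():
    """300 adequately expressed genes; 20 bimodal in a, 29 in b (superset),
    so the census ground truth is a +45% bimodal increase."""
    bimodal = {g: {"a": (5.0, 500.0, 0.5), "b": (5.0, 500.0, 0.5)} for g in range(20)}
    bimodal.update({g: {"a": None, "b": (5.0, 500.0, 0.5)} for g in range(20, 29)})
    spec = cd.CountsModelSpec(
        n_genes=300,
        n_cells_a=300,
        n_cells_b=300,
        mean_law=(2.0, 0.35),
        planted_bimodal=bimodal,
        seed=9,
    )
    counts_a, counts_b, truth = cd.gen_counts(spec)
    return {
        "spec": spec,
        "cpm_a": cd.cpm_normalize(counts_a),
        "cpm_b": cd.cpm_normalize(counts_b),
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_sweep():
    """Scaled-down density sweep of the default telegraph model:
    15 Gamma values in (0, 100), 200 trajectories of 1000 minutes."""
    params = cd.TelegraphParams()
    spec = cd.SweepSpec(
        gamma_values=np.linspace(1.0, 99.0, 15),
        n_trajectories=200,
        t_end_min=1000.0,
        burn_in_min=500.0,
        seed=11,
    )
    return cd.sweep(params, spec)
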