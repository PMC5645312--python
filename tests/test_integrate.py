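"""Differentiation arrows, quadrant fractions, quartile comparison and
profile clustering."""

import numpy as np
import pandas as pd
import pytest

import chromden as cd
from chromden.exceptions import InsufficientDataError, InvalidSpecError


def _toy_inputs(d_gamma, d_cv):
    """Density + CV tables whose per-gene deltas have prescribed signs."""
    n = len(d_gamma)
    genes = [f"g{i}" for i in range(n)]
    density = pd.DataFrame(
        {
            "gene_id": genes,
            "gamma_a": np.full(n, 10.0),
            "gamma_b": 10.0 + np.asarray(d_gamma, dtype=float),
        }
    )
    het_a = pd.DataFrame({"cv": np.full(n, 1.0)}, index=genes)
    het_b = pd.DataFrame({"cv": 1.0 + np.asarray(d_cv, dtype=float)}, index=genes)
    return density, het_a, het_b


class TestArrows:
    def test_identical_conditions_all_ties(self):
        density, het_a, _ = _toy_inputs([0, 0, 0], [0, 0, 0])
        arrows, missing = cd.build_arrows(density, het_a, het_a)
        assert (arrows["quadrant"] == "tie").all()
        assert missing.empty

    def test_planted_signs_give_exact_quadrant_counts(self):
        d_gamma = [1] * 5 + [1] * 3 + [-1] * 2
        d_cv = [1] * 5 + [-1] * 3 + [1] * 2
        density, het_a, het_b = _toy_inputs(d_gamma, d_cv)
        arrows, _ = cd.build_arrows(density, het_a, het_b)
        counts = arrows["quadrant"].value_counts()
        assert counts["++"] == 5 and counts["+-"] == 3 and counts["-+"] == 2

    def test_missing_coordinates_reported(self):
        density, het_a, het_b = _toy_inputs([1, 1], [1, 1])
        het_b.loc["g1", "cv"] = np.nan
        arrows, missing = cd.build_arrows(density, het_a, het_b)
        assert len(arrows) == 1
        assert list(missing["gene_id"]) == ["g1"]

    def test_join_accounting_reconciles(self, counts_world, condensing_world):
        """Every input gene ends up retained, tied, or reported missing."""
        w = condensing_world
        chrom = w["spec"].chromosome
        mats = {"a": {chrom: w["pre"]}, "b": {chrom: w["post"]}}
        density, _ = cd.density_table(mats, w["anno"])
        cpm_a = cd.cpm_normalize(counts_world["a"])
        cpm_b = cd.cpm_normalize(counts_world["b"])
        het_a = cd.gene_stats(cpm_a)
        het_b = cd.gene_stats(cpm_b)
        arrows, missing = cd.build_arrows(density, het_a, het_b)
        assert len(arrows) + len(missing) == len(density)

    def test_empty_join_raises(self):
        density, het_a, het_b = _toy_inputs([1], [1])
        with pytest.raises(InvalidSpecError):
            cd.build_arrows(density, het_a.iloc[:0], het_b.iloc[:0], gene_filter=[])


class TestQuadrantFractions:
    def test_single_arrow(self):
        density, het_a, het_b = _toy_inputs([1], [1])
        arrows, _ = cd.build_arrows(density, het_a, het_b)
        out = cd.quadrant_fractions(arrows)
        assert out["fractions"] == {"++": 1.0}

    def test_planted_83_13_4_split_recovered_exactly(self):
        """A constructed 83/13/4 split at n=100 is recovered exactly."""
        d_gamma = [1] * 83 + [1] * 13 + [-1] * 4
        d_cv = [1] * 83 + [-1] * 13 + [-1] * 4
        density, het_a, het_b = _toy_inputs(d_gamma, d_cv)
        arrows, _ = cd.build_arrows(density, het_a, het_b)
        out = cd.quadrant_fractions(arrows)
        assert out["fractions"]["++"] == pytest.approx(0.83)
        assert out["fractions"]["+-"] == pytest.approx(0.13)
        assert out["fractions"]["--"] == pytest.approx(0.04)
        assert sum(out["fractions"].values()) == pytest.approx(1.0)

    def test_ties_excluded_from_normalization(self):
        d_gamma = [1, 1, 0]
        d_cv = [1, 1, 1]
        density, het_a, het_b = _toy_inputs(d_gamma, d_cv)
        arrows, _ = cd.build_arrows(density, het_a, het_b)
        out = cd.quadrant_fractions(arrows)
        assert out["n_ties"] == 1
        assert out["fractions"]["++"] == 1.0

    def test_no_arrows_rejected(self):
        with pytest.raises(InsufficientDataError):
            cd.quadrant_fractions(pd.DataFrame(columns=["quadrant"]))


class TestDensityByCvClass:
    def _tables(self, shift, n=120, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        flags = np.arange(n) < n // 4
        gamma = rng.integers(10, 20, n).astype(float) + shift * flags
        density = pd.DataFrame({"gene_id": genes, "gamma_a": gamma})
        het = pd.DataFrame({"cv": np.full(n, 1.0), "highcv": flags}, index=genes)
        return density, het

    def test_planted_shift_detected(self):
        density, het = self._tables(shift=10.0)
        qc = cd.density_by_cv_class(density, het)
        assert qc.p_value < 1e-3
        assert (qc.quartiles_high > qc.quartiles_low).all()
        assert (qc.quartiles_high == np.sort(qc.quartiles_high)).all()

    def test_null_classes_similar(self):
        density, het = self._tables(shift=0.0)
        qc = cd.density_by_cv_class(density, het)
        assert qc.p_value > 0.05

    def test_cis_contain_point_estimates_and_are_seeded(self):
        density, het = self._tables(shift=10.0)
        qc1 = cd.density_by_cv_class(density, het, seed=7)
        qc2 = cd.density_by_cv_class(density, het, seed=7)
        np.testing.assert_array_equal(qc1.ci_high, qc2.ci_high)
        assert (qc1.ci_high[0] <= qc1.quartiles_high).all()
        assert (qc1.quartiles_high <= qc1.ci_high[1]).all()

    def test_ci_width_shrinks_with_more_resamples(self):
        density, het = self._tables(shift=10.0, n=400, seed=3)
        wide = cd.density_by_cv_class(density, het, n_boot=100, seed=1)
        narrow = cd.density_by_cv_class(density, het, n_boot=10_000, seed=1)
        assert (narrow.ci_low[1] - narrow.ci_low[0]).mean() <= (
            wide.ci_low[1] - wide.ci_low[0]
        ).mean() + 0.5

    def test_empty_class_named(self):
        density, het = self._tables(shift=0.0)
        het["highcv"] = False
        with pytest.raises(InsufficientDataError, match="high-CV"):
            cd.density_by_cv_class(density, het)


class TestClustering:
    def _profiles(self):
        genes = [f"flat{i}" for i in range(50)] + [f"rise{i}" for i in range(50)]
        flat = np.tile([10.0, 10.0, 10.0], (50, 1)) + np.random.default_rng(0).normal(
            0, 0.3, (50, 3)
        )
        rise = np.tile([5.0, 15.0, 30.0], (50, 1)) + np.random.default_rng(1).normal(
            0, 0.3, (50, 3)
        )
        profiles = np.vstack([flat, rise])
        return pd.DataFrame(
            {
                "gene_id": genes,
                "gamma_a": profiles[:, 0],
                "gamma_b": profiles[:, 1],
                "gamma_c": profiles[:, 2],
            }
        )

    def test_two_archetypes_recovered_exactly(self):
        density = self._profiles()
        labels, _ = cd.cluster_density_changes(density, ["a", "b", "c"], n_clusters=2)
        flat_labels = set(labels[labels.index.str.startswith("flat")])
        rise_labels = set(labels[labels.index.str.startswith("rise")])
        assert len(flat_labels) == 1 and len(rise_labels) == 1
        assert flat_labels != rise_labels

    def test_excluded_genes_absent(self):
        density = self._profiles()
        labels, _ = cd.cluster_density_changes(
            density, ["a", "b", "c"], de_exclusion={"flat0", "rise0"}
        )
        assert "flat0" not in labels.index and "rise0" not in labels.index

    def test_gene_order_permutation_invariant(self):
        density = self._profiles()
        labels1, _ = cd.cluster_density_changes(density, ["a", "b", "c"], n_clusters=2)
        shuffled = density.sample(frac=1.0, random_state=5)
        labels2, _ = cd.cluster_density_changes(shuffled, ["a", "b", "c"], n_clusters=2)
        # label ids may swap; membership partition must be identical
        part1 = labels1.groupby(labels1).groups
        part2 = labels2.groupby(labels2).groups
        sets1 = {frozenset(v) for v in part1.values()}
        sets2 = {frozenset(v) for v in part2.values()}
        assert sets1 == sets2

    def test_too_few_genes_after_exclusion(self):
        density = self._profiles().head(2)
        with pytest.raises(InsufficientDataError):
            cd.cluster_density_changes(
                density, ["a", "b", "c"], de_exclusion={"flat0"}
            )
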