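"""Density-sphere metric: readers, TSS mapping, Gamma, c(R), unit
conversion, and the cross-condition shift test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chromden as cd
from chromden.exceptions import (
    ConfigurationError,
    FormatError,
    InsufficientDataError,
    OutOfRangeError,
)
from chromden.hic import radial_loglog_slope


def _matrix_with_row(row):
    """Symmetric matrix whose 0th row is `row` (diagonal forced to 0)."""
    n = len(row)
    mat = np.zeros((n, n))
    mat[0, :] = row
    mat[:, 0] = row
    mat[0, 0] = 0.0
    return cd.InteractionMatrix(mat, chromosome="chr1")


class TestReader:
    def test_dense_round_trip(self, tmp_path):
        mat = cd.gen_unfolded_polymer_matrix(5)
        path = tmp_path / "m.tsv"
        cd.synthetic.write_interaction_matrix(mat, path, "dense")
        back = cd.read_interaction_matrix(path, "dense")
        np.testing.assert_allclose(back.values, mat.values, rtol=1e-6)

    def test_dense_sidecar_sets_coordinates_and_chromosome(self, tmp_path):
        mat = cd.InteractionMatrix(
            cd.gen_unfolded_polymer_matrix(4).values,
            chromosome="chr7",
            bin_start_coords=np.arange(4) * 40_000 + 800_000,
        )
        path = tmp_path / "m.tsv"
        cd.synthetic.write_interaction_matrix(mat, path, "dense")
        back = cd.read_interaction_matrix(path, "dense")
        assert back.chromosome == "chr7"
        np.testing.assert_array_equal(back.bin_start_coords, mat.bin_start_coords)

    def test_sparse_single_triplet_is_mirrored(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("0 2 0.5\n")
        mat = cd.read_interaction_matrix(path, "sparse")
        assert mat.values[0, 2] == 0.5
        assert mat.values[2, 0] == 0.5
        assert mat.n_bins == 3

    def test_sparse_round_trip(self, tmp_path):
        orig = cd.gen_unfolded_polymer_matrix(6)
        path = tmp_path / "m.tsv"
        cd.synthetic.write_interaction_matrix(orig, path, "sparse")
        back = cd.read_interaction_matrix(path, "sparse", n_bins=6)
        np.testing.assert_allclose(back.values, orig.values, rtol=1e-6)

    def test_non_square_dense_raises_with_shape(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("\n".join("1 1 1 1 1" for _ in range(4)) + "\n")
        with pytest.raises(FormatError, match="4x5"):
            cd.read_interaction_matrix(path, "dense")

    def test_negative_entry_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("0 1 -2\n")
        with pytest.raises(FormatError, match="negative"):
            cd.read_interaction_matrix(path, "sparse")

    def test_zero_matrix_gives_zero_density(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("0 0 0\n0 0 0\n0 0 0\n")
        mat = cd.read_interaction_matrix(path, "dense")
        assert all(cd.compute_gamma(mat, j) == 0 for j in range(3))


class TestTssBin:
    @pytest.fixture
    def matrix(self):
        return cd.gen_unfolded_polymer_matrix(10, chromosome="chr1")

    def test_plus_strand_maps_gene_start(self, matrix):
        gene = {"chromosome": "chr1", "start": 100_000, "end": 180_000, "strand": "+"}
        assert cd.tss_bin(gene, matrix) == 2  # floor(100000 / 40000)

    def test_minus_strand_maps_gene_end(self, matrix):
        gene = {"chromosome": "chr1", "start": 100_000, "end": 180_000, "strand": "-"}
        assert cd.tss_bin(gene, matrix) == 4  # floor(179999 / 40000)

    def test_wrong_chromosome_raises(self, matrix):
        gene = {"chromosome": "chr2", "start": 0, "end": 100, "strand": "+"}
        with pytest.raises(OutOfRangeError):
            cd.tss_bin(gene, matrix)

    def test_tss_beyond_matrix_raises(self, matrix):
        gene = {"chromosome": "chr1", "start": 500_000, "end": 600_000, "strand": "+"}
        with pytest.raises(OutOfRangeError):
            cd.tss_bin(gene, matrix)


class TestComputeGamma:
    def test_hand_enumerated_row_e1(self):
        """IFs {1.0, 0.6, 0.5, 0.4} at e=1 give distances {1, 1.67, 2, 2.5};
        the boundary distance 2.0 is excluded under the strict inequality."""
        mat = _matrix_with_row([0, 1.0, 0.6, 0.5, 0.4])
        assert cd.compute_gamma(mat, 0, cd.DensityParams(R=2, e=1)) == 2

    def test_hand_enumerated_row_e2(self):
        mat = _matrix_with_row([0, 1.0, 0.6, 0.5, 0.4])
        assert cd.compute_gamma(mat, 0, cd.DensityParams(R=2, e=2)) == 1

    def test_literal_printed_form_counts_outside(self):
        """Audit flag: the literal characteristic-function reading counts
        distances greater than R (here only 2.5)."""
        mat = _matrix_with_row([0, 1.0, 0.6, 0.5, 0.4])
        assert cd.compute_gamma(mat, 0, cd.DensityParams(R=2, e=1, literal_form=True)) == 1

    def test_zero_rows_and_range_checks(self):
        mat = cd.InteractionMatrix(np.zeros((4, 4)))
        assert cd.compute_gamma(mat, 1) == 0
        with pytest.raises(IndexError):
            cd.compute_gamma(mat, 4)

    @given(st.integers(0, 10_000), st.sampled_from([1.0, 2.0, 3.0]),
           st.sampled_from([1.0, 2.0, 3.0]))
    @settings(max_examples=40, deadline=None)
    def test_matches_naive_double_loop(self, seed, R, e):
        """Gamma equals a brute-force count over all off-diagonal entries."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        raw = rng.random((n, n)) * rng.integers(0, 2, (n, n))
        mat = cd.InteractionMatrix((raw + raw.T) / 2)
        j = int(rng.integers(0, n))
        expected = sum(
            1
            for i in range(n)
            if i != j and mat.values[i, j] > 0 and (1.0 / mat.values[i, j]) ** e < R
        )
        assert cd.compute_gamma(mat, j, cd.DensityParams(R=R, e=e)) == expected

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_radius(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        raw = rng.random((n, n))
        mat = cd.InteractionMatrix((raw + raw.T) / 2)
        j = int(rng.integers(0, n))
        gammas = [cd.compute_gamma(mat, j, cd.DensityParams(R=R)) for R in (0.5, 1, 2, 3, 5)]
        assert gammas == sorted(gammas)
        assert all(0 <= g <= n - 1 for g in gammas)


class TestRadialProfile:
    def test_direct_formula(self):
        mat = _matrix_with_row([0, 1.0, 0.6, 0.5, 0.4])
        prof = cd.cumulative_radial_profile(mat, 0, e=1.0, R_grid=np.array([2.0]))
        assert prof["gamma"].iloc[0] == 2
        assert prof["c"].iloc[0] == pytest.approx(2 / ((4 / 3) * np.pi * 8), rel=1e-12)

    def test_zero_gamma_gives_zero_c(self):
        mat = cd.InteractionMatrix(np.zeros((4, 4)))
        prof = cd.cumulative_radial_profile(mat, 0, R_grid=np.array([1.0, 2.0]))
        assert (prof["c"] == 0).all()

    def test_unfolded_polymer_inverse_square_law(self):
        """c(R) of a central locus on an unfolded chain falls as 1/R^2."""
        mat = cd.gen_unfolded_polymer_matrix(2001)
        prof = cd.cumulative_radial_profile(mat, 1000, e=1.0, R_grid=np.geomspace(10, 49, 30))
        assert abs(radial_loglog_slope(prof)) == pytest.approx(2.0, abs=0.05)

    def test_invalid_grid_rejected(self):
        mat = cd.gen_unfolded_polymer_matrix(5)
        with pytest.raises(ValueError):
            cd.cumulative_radial_profile(mat, 0, R_grid=np.array([-1.0, 2.0]))


class TestDensityTable:
    def test_identical_conditions_identical_columns(self, condensing_world):
        w = condensing_world
        mats = {"a": {w["spec"].chromosome: w["pre"]}, "b": {w["spec"].chromosome: w["pre"]}}
        table, skipped = cd.density_table(mats, w["anno"].head(30))
        assert (table["gamma_a"] == table["gamma_b"]).all()
        assert skipped.empty

    def test_empty_annotation_gives_empty_table(self, condensing_world):
        w = condensing_world
        mats = {"a": {w["spec"].chromosome: w["pre"]}}
        table, _ = cd.density_table(mats, w["anno"].iloc[:0])
        assert table.empty

    def test_unmappable_gene_reported_not_dropped(self, condensing_world):
        w = condensing_world
        mats = {"a": {w["spec"].chromosome: w["pre"]}}
        anno = pd.concat(
            [
                w["anno"].head(3),
                pd.DataFrame(
                    [{"gene_id": "ghost", "chromosome": w["spec"].chromosome,
                      "start": 10**9, "end": 10**9 + 100, "strand": "+"}]
                ),
            ],
            ignore_index=True,
        )
        table, skipped = cd.density_table(mats, anno)
        assert len(table) == 3
        assert list(skipped["gene_id"]) == ["ghost"]

    def test_missing_chromosome_matrix_raises(self, condensing_world):
        w = condensing_world
        with pytest.raises(ConfigurationError, match="lacks matrices"):
            cd.density_table({"a": {}}, w["anno"].head(2))

    def test_condensation_increases_density_only_at_hotspots(self, condensing_world):
        """Planted condensation raises Gamma at hotspot-bin genes and
        nowhere else (hotspots shrink only within-block distances)."""
        w = condensing_world
        chrom = w["spec"].chromosome
        mats = {"a": {chrom: w["pre"]}, "b": {chrom: w["post"]}}
        table, _ = cd.density_table(mats, w["anno"])
        delta = table["gamma_b"] - table["gamma_a"]
        in_hot = table["tss_bin"].isin(w["hotspots"])
        assert (delta[~in_hot] == 0).all()
        assert (delta[in_hot] > 0).mean() > 0.9


class TestDensityShift:
    def test_identical_columns_null_result(self):
        table = pd.DataFrame({"gamma_a": [1, 2, 3], "gamma_b": [1, 2, 3]})
        med, p, direction = cd.compare_density_shift(table, "a", "b")
        assert (med, direction) == (0.0, "none")
        assert p == pytest.approx(1.0)

    def test_constant_unit_shift_exact_signed_rank(self):
        """A +1 shift for all 6 genes gives the exact two-sided signed-rank
        p-value 2/2^6 = 0.03125."""
        table = pd.DataFrame({"gamma_a": [3, 4, 5, 6, 7, 8], "gamma_b": [4, 5, 6, 7, 8, 9]})
        med, p, direction = cd.compare_density_shift(table, "a", "b")
        assert direction == "increase"
        assert med == 1.0
        assert p == pytest.approx(0.03125, rel=1e-9)

    def test_too_few_genes_raises(self):
        table = pd.DataFrame({"gamma_a": [1], "gamma_b": [2]})
        with pytest.raises(InsufficientDataError):
            cd.compare_density_shift(table, "a", "b")

    @pytest.mark.parametrize("R", [1.0, 2.0, 3.0])
    def test_condensing_shift_significant_and_robust_in_R(self, condensing_world, R):
        """The condensation signal is significant (p < 0.001) with the same
        direction for R in 1..3."""
        w = condensing_world
        chrom = w["spec"].chromosome
        mats = {"a": {chrom: w["pre"]}, "b": {chrom: w["post"]}}
        table, _ = cd.density_table(mats, w["anno"], cd.DensityParams(R=R, e=1))
        med, p, direction = cd.compare_density_shift(table, "a", "b")
        assert direction == "increase"
        assert p < 1e-3


class TestPhysicalScale:
    def test_mean_density_maps_to_tad_scale(self):
        """Twenty 40-kb bins of DNA at nuclear density fill a sphere of
        roughly 250 nm, the scale of an average TAD."""
        assert cd.physical_radius(20.0) == pytest.approx(249.5, abs=1.0)

    def test_cube_root_scaling(self):
        assert cd.physical_radius(8 * 5.0) == pytest.approx(2 * cd.physical_radius(5.0))

    def test_density_inverse_cube_root(self):
        dense = cd.PhysicalScale(nuclear_density_bp_per_nm3=2 * 0.0123)
        assert cd.physical_radius(5.0, scale=dense) == pytest.approx(
            cd.physical_radius(5.0) / 2 ** (1 / 3)
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cd.physical_radius(0.0)
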