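import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import smncent as sc
from smncent.errors import DegenerateMapError, ParameterError

from conftest import mask_of_size, random_standardized


def _exact_corr_mask(C_target: np.ndarray) -> sc.VoxelMatrix:
    """Time series on a 3-voxel mask realising an exact +/-1 correlation block."""
    mask = mask_of_size(3)
    t = np.linspace(0, 1, 8)
    s = np.sin(2 * np.pi * t)
    rows = np.stack([sign * s for sign in C_target])
    return sc.VoxelMatrix(mask, rows)


class TestStandardize:
    def test_mean_zero_sum_squares(self):
        mask = mask_of_size(1)
        vm = sc.VoxelMatrix(mask, np.array([[1.0, 2.0, 3.0, 4.0]]))
        zvm, flagged = sc.standardize_rows(vm)
        assert flagged.size == 0
        assert zvm.data.mean() == pytest.approx(0.0, abs=1e-12)
        assert (zvm.data**2).sum() == pytest.approx(3.0)  # T - 1

    def test_proportional_rows_correlate_fully(self):
        mask = mask_of_size(2)
        base = np.array([0.5, -1.0, 2.0, 0.1, 3.0])
        vm = sc.VoxelMatrix(mask, np.stack([base, 4.0 * base]))
        zvm, _ = sc.standardize_rows(vm)
        r = zvm.data[0] @ zvm.data[1] / (5 - 1)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_dot_products_match_pearson_oracle(self):
        rng = np.random.default_rng(0)
        mask = mask_of_size(20)
        X = rng.normal(size=(20, 50))
        zvm, _ = sc.standardize_rows(sc.VoxelMatrix(mask, X))
        C = zvm.data @ zvm.data.T / 49
        np.testing.assert_allclose(C, np.corrcoef(X), atol=1e-10)

    def test_zero_variance_flagged_and_zeroed(self):
        mask = mask_of_size(3)
        X = np.random.default_rng(1).normal(size=(3, 10))
        X[1] = 2.5
        zvm, flagged = sc.standardize_rows(sc.VoxelMatrix(mask, X))
        np.testing.assert_array_equal(flagged, [1])
        assert np.all(zvm.data[1] == 0.0)
        dc = sc.degree_centrality(zvm, 0.25)
        assert dc.values[1] == 0.0


class TestDegreeCentrality:
    def test_constructed_three_voxel_case(self):
        vm = _exact_corr_mask(np.array([1.0, 1.0, -1.0]))
        zvm, _ = sc.standardize_rows(vm)
        dc = sc.degree_centrality(zvm, r0=0.25)
        np.testing.assert_allclose(dc.values, [1.0, 1.0, 0.0], atol=1e-10)

    def test_identical_series_saturate(self):
        mask = mask_of_size(6)
        vm = sc.VoxelMatrix(mask, np.tile(np.sin(np.arange(9.0)), (6, 1)))
        zvm, _ = sc.standardize_rows(vm)
        dc = sc.degree_centrality(zvm, 0.25)
        np.testing.assert_allclose(dc.values, 5.0, atol=1e-10)
        binary = sc.degree_centrality(zvm, 0.25, mode="binary")
        np.testing.assert_allclose(binary.values, 5.0, atol=1e-12)

    @pytest.mark.parametrize("block_size", [1, 7, 50, 1024])
    def test_blockwise_matches_dense_oracle(self, block_size):
        zvm = random_standardized(mask_of_size(50), T=40, seed=2)
        C = np.corrcoef(zvm.data)
        np.fill_diagonal(C, 0.0)
        expected = np.where(C > 0.25, C, 0.0).sum(axis=1)
        dc = sc.degree_centrality(zvm, 0.25, block_size=block_size)
        np.testing.assert_allclose(dc.values, expected, atol=1e-10)

    def test_monotone_in_threshold(self):
        zvm = random_standardized(mask_of_size(40), T=30, seed=3)
        maps = sc.multi_threshold_dc(zvm, sc.ThresholdSet((0.1, 0.25, 0.4)))
        assert np.all(maps[2].values <= maps[1].values + 1e-12)
        assert np.all(maps[1].values <= maps[0].values + 1e-12)

    def test_multi_threshold_consistent_with_single(self):
        zvm = random_standardized(mask_of_size(30), T=25, seed=4)
        multi = sc.multi_threshold_dc(zvm, sc.ThresholdSet((0.25,)))[0]
        single = sc.degree_centrality(zvm, 0.25)
        np.testing.assert_array_equal(multi.values, single.values)

    def test_invalid_threshold_rejected(self):
        zvm = random_standardized(mask_of_size(5), T=10, seed=5)
        with pytest.raises(ParameterError):
            sc.degree_centrality(zvm, 1.5)
        with pytest.raises(ParameterError):
            sc.multi_threshold_dc(zvm, sc.ThresholdSet(()))

    def test_requires_standardized_input(self):
        mask = mask_of_size(4)
        vm = sc.VoxelMatrix(mask, np.random.default_rng(0).normal(size=(4, 10)))
        with pytest.raises(ParameterError):
            sc.degree_centrality(vm, 0.25)


class TestEigenvectorCentrality:
    def test_hand_computed_block_case(self):
        """C = [[1,1,-1],[1,1,-1],[-1,-1,1]] -> A blocks {1,2},{3}; v=(1,1,0)/sqrt2."""
        vm = _exact_corr_mask(np.array([1.0, 1.0, -1.0]))
        zvm, _ = sc.standardize_rows(vm)
        ec = sc.fast_eigenvector_centrality(zvm)
        np.testing.assert_allclose(
            ec.values, [1 / np.sqrt(2), 1 / np.sqrt(2), 0.0], atol=1e-8
        )
        assert ec.lambda1 == pytest.approx(2.0, abs=1e-8)
        assert ec.converged

    def test_identical_voxels_uniform(self):
        mask = mask_of_size(8)
        vm = sc.VoxelMatrix(mask, np.tile(np.cos(np.arange(12.0)), (8, 1)))
        zvm, _ = sc.standardize_rows(vm)
        ec = sc.fast_eigenvector_centrality(zvm)
        np.testing.assert_allclose(ec.values, 1 / np.sqrt(8), atol=1e-10)

    def test_matches_dense_eigensolver(self):
        zvm = random_standardized(mask_of_size(40), T=30, seed=6)
        ec = sc.fast_eigenvector_centrality(zvm)
        C = np.corrcoef(zvm.data)
        A = (C + 1.0) / 2.0
        w, V = np.linalg.eigh(A)
        dense = np.abs(V[:, -1])
        cosine = abs(ec.values @ dense)
        assert cosine > 1 - 1e-8
        assert ec.lambda1 == pytest.approx(w[-1], rel=1e-8)

    def test_nonnegative_unit_norm(self):
        for seed in range(5):
            zvm = random_standardized(mask_of_size(25), T=20, seed=seed)
            ec = sc.fast_eigenvector_centrality(zvm)
            assert np.all(ec.values >= 0.0)
            assert np.linalg.norm(ec.values) == pytest.approx(1.0, abs=1e-12)

    def test_nonconvergence_warns(self):
        zvm = random_standardized(mask_of_size(30), T=25, seed=7)
        with pytest.warns(RuntimeWarning):
            ec = sc.fast_eigenvector_centrality(zvm, tol=0.0, max_iter=3)
        assert ec.converged is False


class TestPermutationEquivariance:
    def test_dc_and_ec_permute_with_voxels(self):
        mask = mask_of_size(30)
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 40))
        perm = rng.permutation(30)
        z1, _ = sc.standardize_rows(sc.VoxelMatrix(mask, X))
        z2, _ = sc.standardize_rows(sc.VoxelMatrix(mask, X[perm]))
        np.testing.assert_allclose(
            sc.degree_centrality(z2, 0.25).values,
            sc.degree_centrality(z1, 0.25).values[perm],
            atol=1e-10,
        )
        np.testing.assert_allclose(
            sc.fast_eigenvector_centrality(z2).values,
            sc.fast_eigenvector_centrality(z1).values[perm],
            atol=1e-8,
        )


class TestNormalisation:
    def _map(self, values):
        mask = mask_of_size(len(values))
        return sc.CentralityMap(mask, np.asarray(values, float), metric="DC", r0=0.25)

    def test_global_mean_arithmetic(self):
        out = sc.normalize_global_mean(self._map([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.values, [0.5, 1.0, 1.5])
        assert out.values.mean() == pytest.approx(1.0, abs=1e-12)
        assert out.normalization == ["raw", "global_mean"]

    def test_constant_map_to_ones(self):
        out = sc.normalize_global_mean(self._map([4.0, 4.0, 4.0]))
        np.testing.assert_allclose(out.values, 1.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(DegenerateMapError):
            sc.normalize_global_mean(self._map([-1.0, 1.0]))

    def test_fisher_z_closed_forms(self):
        out = sc.convert_for_group(self._map([0.0, 0.5, -0.5]), "fisher_z")
        np.testing.assert_allclose(
            out.values, [0.0, 0.5 * np.log(3.0), -0.5 * np.log(3.0)], atol=1e-12
        )

    def test_fisher_z_domain_error(self):
        with pytest.raises(DegenerateMapError, match="z_standardize"):
            sc.convert_for_group(self._map([0.5, 1.2]), "fisher_z")

    def test_z_standardize_moments(self):
        out = sc.convert_for_group(self._map([3.0, 1.0, 4.0, 1.0, 5.0]), "z_standardize")
        assert out.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.values.std() == pytest.approx(1.0, abs=1e-12)

    def test_rank_gauss_monotone(self):
        out = sc.rank_gauss(self._map([0.1, 0.7, 2.0, 5.0]))
        assert np.all(np.diff(out.values) > 0)

    def test_rank_gauss_ties_to_zero(self):
        out = sc.rank_gauss(self._map([2.0, 2.0, 2.0]))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_rank_gauss_blom_positions_n3(self):
        out = sc.rank_gauss(self._map([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(out.values, [-0.869, 0.0, 0.869], atol=1e-3)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), r0=st.floats(0.05, 0.9))
def test_dc_threshold_monotonicity_property(seed, r0):
    """Raising r0 never increases any voxel's DC (property over random data)."""
    zvm = random_standardized(mask_of_size(15), T=12, seed=seed)
    lo = sc.degree_centrality(zvm, r0 * 0.5).values
    hi = sc.degree_centrality(zvm, r0).values
    assert np.all(hi <= lo + 1e-12)
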