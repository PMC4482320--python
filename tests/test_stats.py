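import numpy as np
import pytest
from scipy import ndimage
from scipy import stats as sps

import smncent as sc
from smncent.errors import ConfigurationError, ParameterError

from conftest import mask_of_size


def _mask(n=30, seed=0):
    return mask_of_size(n, seed=seed)


class TestGlmTmap:
    def test_identical_groups_give_zero_t(self):
        mask = _mask(10)
        Y = np.tile(np.arange(10.0), (8, 1))
        design = sc.make_group_design(np.repeat([0.0, 1.0], 4))
        tmap = sc.glm_tmap(Y, design, mask)
        # zero between-group difference; every voxel also has zero residual
        # variance, so statistics are flagged rather than numeric zeros
        assert tmap.flagged.size == 10

    def test_matches_pooled_two_sample_oracle(self):
        rng = np.random.default_rng(0)
        mask = _mask(25)
        Y = rng.normal(size=(8, 25))
        group = np.repeat([0.0, 1.0], 4)
        design = sc.make_group_design(group)
        tmap = sc.glm_tmap(Y, design, mask)
        t_ref = sps.ttest_ind(Y[4:], Y[:4], axis=0, equal_var=True).statistic
        np.testing.assert_allclose(tmap.values, t_ref, atol=1e-10)
        assert tmap.dof == 6

    def test_t_squared_equals_ancova_partial_f(self):
        rng = np.random.default_rng(1)
        mask = _mask(12)
        n = 16
        Y = rng.normal(size=(n, 12))
        group = np.repeat([0.0, 1.0], n // 2)
        age = rng.uniform(20, 60, n)
        gender = rng.integers(2, size=n).astype(float)
        tmap = sc.glm_tmap(Y, sc.make_group_design(group, age, gender), mask)
        fmap = sc.ancova_fmap(
            Y, np.where(group == 1, "b", "a"), mask,
            covariates=np.column_stack([age, gender]),
        )
        np.testing.assert_allclose(tmap.values**2, fmap.values, atol=1e-8)


class TestPairedTmap:
    def test_identical_maps_flagged(self):
        mask = _mask(6)
        Y = np.random.default_rng(2).normal(size=(5, 6))
        tmap = sc.paired_tmap(Y, Y, mask)
        assert tmap.flagged.size == 6

    def test_hand_computed_differences(self):
        """Differences (1,2,3): mean 2, sd 1, se 1/sqrt(3), t ~ 3.464, dof 2."""
        mask = _mask(1)
        Ya = np.zeros((3, 1))
        Yb = np.array([[1.0], [2.0], [3.0]])
        tmap = sc.paired_tmap(Ya, Yb, mask)
        assert tmap.values[0] == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-10)
        assert tmap.values[0] == pytest.approx(3.464, abs=1e-3)
        assert tmap.dof == 2

    def test_equals_subject_fixed_effects_glm(self):
        rng = np.random.default_rng(3)
        mask = _mask(8)
        n = 6
        Ya = rng.normal(size=(n, 8))
        Yb = Ya + rng.normal(0.3, 0.5, size=(n, 8))
        paired = sc.paired_tmap(Ya, Yb, mask)
        # equivalent GLM: stack sessions, subject dummies + session column
        Y = np.vstack([Ya, Yb])
        session = np.repeat([0.0, 1.0], n)
        subj = np.vstack([np.eye(n), np.eye(n)])
        X = np.column_stack([subj, session])
        names = tuple(f"s{i}" for i in range(n)) + ("session",)
        contrast = np.zeros(n + 1)
        contrast[-1] = 1.0
        glm = sc.glm_tmap(Y, sc.DesignMatrix(X, names, contrast), mask)
        np.testing.assert_allclose(glm.values, paired.values, atol=1e-8)


class TestAncova:
    def test_identical_groups_f_near_zero(self):
        mask = _mask(5)
        base = np.random.default_rng(4).normal(size=(4, 5))
        Y = np.vstack([base, base, base])
        labels = np.repeat(["a", "b", "c"], 4)
        fmap = sc.ancova_fmap(Y, labels, mask)
        ok = np.setdiff1d(np.arange(5), fmap.flagged)
        np.testing.assert_allclose(fmap.values[ok], 0.0, atol=1e-8)

    def test_matches_one_way_anova_oracle(self):
        rng = np.random.default_rng(5)
        mask = _mask(10)
        Y = rng.normal(size=(12, 10))
        labels = np.repeat(["a", "b", "c"], 4)
        fmap = sc.ancova_fmap(Y, labels, mask)
        f_ref = sps.f_oneway(Y[:4], Y[4:8], Y[8:], axis=0).statistic
        np.testing.assert_allclose(fmap.values, f_ref, atol=1e-10)
        assert fmap.df_num == 2 and fmap.dof == 9


class TestNeighborhood:
    def test_3mm_rmm5_is_18_connectivity(self):
        offs = sc.neighbors_from_rmm(3.0, 5.0)
        assert len(offs) == 18
        dists = np.linalg.norm(offs * 3.0, axis=1)
        assert dists.max() <= 5.0

    def test_3mm_rmm3_faces_only(self):
        assert len(sc.neighbors_from_rmm(3.0, 3.0)) == 6

    def test_1mm_rmm_1p8_full_26(self):
        assert len(sc.neighbors_from_rmm(1.0, 1.8)) == 26

    def test_rmm_below_voxel_size_rejected(self):
        with pytest.raises(ParameterError):
            sc.neighbors_from_rmm(3.0, 2.0)


def _statmap_from_binary(field: np.ndarray, mask: sc.BrainMask, value=10.0):
    vals = np.where(field.ravel()[mask.linear_indices] > 0, value, 0.0)
    return sc.StatMap(mask, vals, dof=20, kind="t")


class TestClusterLabeling:
    def test_no_supra_threshold_voxels(self):
        mask = _mask(20)
        sm = sc.StatMap(mask, np.zeros(20), dof=10)
        res = sc.label_clusters(sm, voxel_p=0.01)
        assert res.clusters == []

    def test_corner_touching_blobs_split_under_18_connectivity(self):
        grid = sc.ImageGrid.from_voxel_size((6, 6, 6), 3.0)
        mask = sc.BrainMask(grid, np.ones(grid.shape, bool))
        field = np.zeros(grid.shape)
        field[1, 1, 1] = field[1, 1, 2] = 1.0  # blob A
        field[2, 2, 3] = field[2, 2, 4] = 1.0  # blob B touches A only at a corner
        sm = _statmap_from_binary(field, mask)
        res18 = sc.label_clusters(sm, voxel_p=0.01, rmm=5.0)  # 18-connectivity
        assert len(res18.clusters) == 2
        res26 = sc.label_clusters(sm, voxel_p=0.01, rmm=5.2)  # corners included
        assert len(res26.clusters) == 1

    def test_cluster_order_and_peaks(self):
        grid = sc.ImageGrid.from_voxel_size((6, 6, 6), 3.0)
        mask = sc.BrainMask(grid, np.ones(grid.shape, bool))
        vals = np.zeros(mask.n_voxels)
        lins = mask.linear_indices
        vals[:3] = [5.0, 6.0, 5.5]  # cluster of 3 (contiguous C-order = z axis)
        vals[100] = 7.0  # singleton with higher peak
        sm = sc.StatMap(mask, vals, dof=30)
        res = sc.label_clusters(sm, voxel_p=0.01, rmm=3.0)
        assert [c.size for c in res.clusters] == [3, 1]
        assert res.clusters[0].peak_stat == 6.0
        assert res.clusters[0].peak_voxel == lins[1]
        assert res.clusters[1].peak_stat == 7.0

    def test_negative_tail_labelled_separately(self):
        mask = _mask(30)
        vals = np.zeros(30)
        vals[0] = 8.0
        vals[10] = -8.0
        sm = sc.StatMap(mask, vals, dof=15)
        res = sc.label_clusters(sm, voxel_p=0.01, tail="both")
        tails = sorted(c.tail for c in res.clusters)
        assert tails == ["neg", "pos"]
        only_pos = sc.label_clusters(sm, voxel_p=0.01, tail="pos")
        assert [c.tail for c in only_pos.clusters] == ["pos"]

    @pytest.mark.parametrize("rmm,conn", [(3.0, 1), (4.3, 2), (5.2, 3)])
    def test_agrees_with_ndimage_flood_fill(self, rmm, conn):
        """Component counts match scipy's labelling for all three connectivities."""
        rng = np.random.default_rng(6)
        grid = sc.ImageGrid.from_voxel_size((8, 8, 8), 3.0)
        mask = sc.BrainMask(grid, np.ones(grid.shape, bool))
        for _ in range(20):
            field = rng.random(grid.shape) < 0.2
            if not field.any():
                continue
            sm = _statmap_from_binary(field.astype(float), mask)
            res = sc.label_clusters(sm, voxel_p=0.01, rmm=rmm)
            structure = ndimage.generate_binary_structure(3, conn)
            _, n_ref = ndimage.label(field, structure=structure)
            assert len(res.clusters) == n_ref
            assert sum(c.size for c in res.clusters) == int(field.sum())


class TestAlphaSim:
    def test_alpha_one_gives_k_one(self):
        mask = _mask(200, seed=1)
        asr = sc.alphasim_threshold(mask, fwhm_mm=0.0, iterations=100, seed=0)
        assert asr.k_for(1.0) == 1

    def test_unsmoothed_independent_regime(self):
        """fwhm 0, p=0.01, 1000-voxel mask: max null cluster stays tiny."""
        mask = mask_of_size(1000, seed=2)
        asr = sc.alphasim_threshold(
            mask, fwhm_mm=0.0, voxel_p=0.01, rmm=5.0, iterations=1000, seed=3
        )
        assert asr.critical_k in (1, 2, 3)

    def test_smoothing_inflates_critical_k(self):
        mask = mask_of_size(600, seed=3)
        hits = 0
        for seed in range(5):
            k0 = sc.alphasim_threshold(mask, 0.0, iterations=200, seed=seed).critical_k
            k6 = sc.alphasim_threshold(mask, 6.0, iterations=200, seed=seed).critical_k
            hits += k6 >= k0
        assert hits == 5

    def test_deterministic_per_seed(self):
        mask = _mask(150, seed=4)
        a = sc.alphasim_threshold(mask, 6.0, iterations=100, seed=9)
        b = sc.alphasim_threshold(mask, 6.0, iterations=100, seed=9)
        np.testing.assert_array_equal(a.null_max_sizes, b.null_max_sizes)
        assert a.critical_k == b.critical_k

    def test_alpha_to_k_nonincreasing(self):
        mask = _mask(300, seed=5)
        asr = sc.alphasim_threshold(mask, 6.0, iterations=200, seed=1)
        ks = [asr.k_for(a) for a in (0.2, 0.1, 0.05, 0.01)]
        assert all(b >= a for a, b in zip(ks, ks[1:]))


class TestClusterCorrection:
    def test_boundary_sizes(self):
        mask = mask_of_size(60, seed=7)
        c20 = sc.Cluster(np.arange(20), 5.0, 0, "pos")
        c19 = sc.Cluster(np.arange(100, 119), 5.0, 100, "pos")
        clusters = sc.ClusterResult(mask, [c20, c19], 0.01, 2.5, 5.0)
        asr = sc.AlphaSimResult(0.01, 6.0, 5.0, 1000, 0.05, 20,
                                np.full(1000, 19), {0.05: 20})
        out = sc.apply_cluster_correction(clusters, asr, 0.05)
        assert out.clusters[0].surviving is True  # size 20 >= k 20
        assert out.clusters[1].surviving is False  # size 19 < k 20

    def test_k_one_everything_survives(self):
        mask = mask_of_size(60, seed=8)
        c = sc.Cluster(np.arange(3), 5.0, 0, "pos")
        clusters = sc.ClusterResult(mask, [c], 0.01, 2.5, 5.0)
        asr = sc.AlphaSimResult(0.01, 6.0, 5.0, 1000, 0.05, 1,
                                np.zeros(1000, int), {0.05: 1})
        out = sc.apply_cluster_correction(clusters, asr)
        assert all(cl.surviving for cl in out.clusters)

    def test_inconsistent_parameters_rejected(self):
        mask = mask_of_size(60, seed=9)
        clusters = sc.ClusterResult(mask, [], 0.05, 2.0, 5.0)
        asr = sc.AlphaSimResult(0.01, 6.0, 5.0, 1000, 0.05, 5,
                                np.zeros(1000, int), {})
        with pytest.raises(ConfigurationError):
            sc.apply_cluster_correction(clusters, asr)
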