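"""Voxelwise GLM detection, thresholding, Dice and voxel counts."""

import numpy as np
import pytest
from scipy.stats import kstest

from hrfpipe import (BlockParadigm, DesignMatrix, MOUSE, smooth_spatial,
                     fit_glm, task_statistic, threshold_map,
                     activation_probability, dice, count_activated_voxels,
                     build_canonical_design)


def toy_design(n=20, rng=None):
    rng = rng or np.random.default_rng(0)
    task = rng.random(n)
    return DesignMatrix(np.column_stack([task, np.ones(n)]),
                        ["task_hrf", "intercept"], task_columns=[0])


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng):
        data = rng.random((6, 6, 4, 3))
        assert np.array_equal(smooth_spatial(data, (0, 0, 0)), data)

    def test_constant_volume_unchanged(self):
        data = np.full((8, 8, 4, 2), 3.7)
        out = smooth_spatial(data, (4.0, 4.0, 10.0))
        assert np.allclose(out, 3.7)

    def test_point_source_matches_separable_1d_profile(self):
        from scipy.ndimage import gaussian_filter1d
        data = np.zeros((21, 21, 21, 1))
        data[10, 10, 10, 0] = 1.0
        fwhm = 4.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        out = smooth_spatial(data, (fwhm, fwhm, fwhm))[..., 0]
        imp = np.zeros(21)
        imp[10] = 1.0
        prof = gaussian_filter1d(imp, sigma)
        want = prof[:, None, None] * prof[None, :, None] * prof[None, None, :]
        assert np.allclose(out, want, atol=1e-12)


class TestFitGLM:
    def test_recovers_known_betas_noise_free(self, rng):
        dm = toy_design(30, rng)
        true_b = rng.normal(size=(4, 4, 2, 2))
        data = np.einsum("xyzp,np->xyzn", true_b, dm.matrix)
        betas, rss, df = fit_glm(data, dm)
        assert np.allclose(betas, true_b, atol=1e-10)
        assert np.allclose(rss, 0, atol=1e-18)
        assert df == 28

    def test_matches_hand_computed_normal_equations(self):
        X = np.array([[1.0, 1], [2, 1], [3, 1], [4, 1]])
        dm = DesignMatrix(X, ["task_hrf", "intercept"], task_columns=[0])
        y = np.array([[1.0, 2.0, 2.0, 4.0], [0.0, 1.0, 0.0, 1.0]])
        data = y.reshape(2, 1, 1, 4)
        betas, rss, df = fit_glm(data, dm)
        want = np.linalg.inv(X.T @ X) @ X.T @ y.T    # 4x2 algebra oracle
        assert np.allclose(betas.reshape(2, 2), want.T, atol=1e-12)
        resid = y.T - X @ want
        assert np.allclose(rss.ravel(), (resid ** 2).sum(axis=0))
        assert df == 2

    def test_intercept_only_gives_time_mean(self, rng):
        dm = DesignMatrix(np.ones((10, 1)), ["intercept"])
        data = rng.random((3, 3, 2, 10))
        betas, _, _ = fit_glm(data, dm)
        assert np.allclose(betas[..., 0], data.mean(axis=-1))

    def test_wrong_volume_count_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_glm(rng.random((2, 2, 2, 5)), toy_design(20))


class TestTaskStatistic:
    def test_degenerate_noise_free_voxel(self):
        dm = toy_design(20)
        data = np.full((2, 2, 1, 20), 5.0)   # intercept fits exactly
        betas, rss, _ = fit_glm(data, dm)
        stat = task_statistic(betas, rss, dm)
        assert np.all(stat.values == 0)
        assert np.all(stat.p == 1.0)

    def test_t_squared_equals_f(self, rng):
        dm = toy_design(25, rng)
        data = (2.0 * dm.matrix[:, 0] + rng.normal(size=(3, 3, 2, 25)))
        betas, rss, _ = fit_glm(data, dm)
        t_map = task_statistic(betas, rss, dm, kind="t")
        f_map = task_statistic(betas, rss, dm, kind="F")
        assert np.allclose(t_map.values ** 2, f_map.values, rtol=1e-10)

    def test_null_p_uniform(self, rng):
        par = BlockParadigm(n_blocks=4)
        dm = build_canonical_design(par, MOUSE, order=1, n_volumes=120,
                                    drift=False)
        data = rng.normal(size=(10, 10, 10, 120))
        betas, rss, _ = fit_glm(data, dm)
        stat = task_statistic(betas, rss, dm)
        res = kstest(stat.p.ravel(), "uniform")
        assert res.pvalue > 0.01


class TestThreshold:
    @staticmethod
    def _statmap_from_mask(sig_mask):
        p = np.where(sig_mask, 0.001, 0.9)
        vals = np.where(sig_mask, 10.0, 0.0)
        from hrfpipe import StatMap
        return StatMap(values=vals, p=p, kind="t", df=(100,))

    def test_cluster_of_five_removed_six_retained(self):
        sig = np.zeros((12, 12, 4), dtype=bool)
        sig[1, 1:6, 1] = True            # 5-voxel line cluster
        sig[8, 2:8, 2] = True            # 6-voxel line cluster
        mask = threshold_map(self._statmap_from_mask(sig),
                             alpha=0.05, min_cluster=5)
        assert not mask[1, 1:6, 1].any()
        assert mask[8, 2:8, 2].all()

    def test_diagonal_voxels_not_connected(self):
        # 6-connectivity: face neighbors only, diagonals split clusters
        sig = np.zeros((10, 10, 4), dtype=bool)
        for i in range(6):
            sig[i, i, 1] = True
        mask = threshold_map(self._statmap_from_mask(sig), min_cluster=5)
        assert not mask.any()

    def test_empty_map_gives_empty_mask(self):
        sig = np.zeros((6, 6, 3), dtype=bool)
        mask = threshold_map(self._statmap_from_mask(sig))
        assert not mask.any()


class TestMaskOps:
    def test_activation_probability_cases(self):
        a = np.zeros((4, 4, 2), bool)
        a[0, 0, 0] = True
        b = ~a
        assert np.allclose(activation_probability([a, a]), a.astype(float))
        assert np.allclose(activation_probability([a, b]), 0.5)
        k_of_n = activation_probability([a, a, b, b, b])
        assert k_of_n[0, 0, 0] == pytest.approx(0.4)
        with pytest.raises(ValueError):
            activation_probability([])

    def test_dice_cases(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0, :4, 0] = True
        b[1, :4, 0] = True
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0
        b[1, :, 0] = False
        b[0, 2:4, 0] = True
        b[1, 0:2, 0] = True                # |A|=4 |B|=4 overlap 2
        assert dice(a, b) == 0.5
        assert dice(a, b) == dice(b, a)
        assert dice(np.zeros_like(a), np.zeros_like(a)) == 1.0

    def test_counts_match_manual_tally(self):
        labels = np.zeros((6, 6, 2), dtype=int)
        labels[:2, :2, 0] = 1
        labels[3:5, 3:5, 0] = 2
        labels[0:3, 4:6, 1] = 3
        mask = np.zeros_like(labels, dtype=bool)
        mask[0, 0, 0] = True             # 1 voxel of structure 1
        mask[3:5, 3, 0] = True           # 2 voxels of structure 2
        table = count_activated_voxels(mask, labels)
        assert table.set_index("structure")["n_active"].to_dict() == {
            1: 1, 2: 2, 3: 0}
        full = count_activated_voxels(np.ones_like(mask, bool), labels)
        assert (full["n_active"] == full["n_voxels"]).all()
        empty = count_activated_voxels(np.zeros_like(mask, bool), labels)
        assert (empty["n_active"] == 0).all()
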