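"""Voxelwise GLM, z conversion, smoothing, smoothness and clusters."""

import numpy as np
import pytest
from scipy import ndimage, stats as sps

from pnvf.stats import (
    StatsError,
    build_design,
    calibrate_cluster_threshold,
    estimate_smoothness,
    extract_clusters,
    smooth_z,
    t_to_z,
    voxel_glm,
)


def _mask(shape):
    return np.ones(shape, bool)


class TestVoxelGlm:
    def test_degrees_of_freedom_with_repeat_scan_reduction(self, rng):
        # 88 rows, 4-column design, df reduced by 3 for repeat scans
        maps = rng.normal(0, 1, (88, 3, 3, 3))
        X = np.column_stack([np.ones(88), rng.integers(0, 2, 88),
                             rng.normal(15, 4, 88), rng.integers(0, 2, 88)])
        res = voxel_glm(maps, X, [0, 1, 0, 0], _mask((3, 3, 3)), df_reduction=3)
        assert res.df == 81

    def test_perfect_fit_reports_capped_t(self):
        pred = np.arange(10.0)
        maps = np.tile(pred[:, None, None, None], (1, 2, 2, 1))
        X = np.column_stack([np.ones(10), pred])
        res = voxel_glm(maps, X, [0, 1], _mask((2, 2, 1)))
        assert (np.abs(res.t[_mask((2, 2, 1))]) == 1e6).all()

    def test_null_predictor_t_calibrated(self, rng):
        n, V = 40, 4000
        maps = rng.normal(0, 1, (n, V, 1, 1))
        X = np.column_stack([np.ones(n), rng.permutation(np.repeat([0, 1], n // 2))])
        res = voxel_glm(maps, X, [0, 1], _mask((V, 1, 1)))
        crit = sps.t.ppf(0.975, res.df)
        frac = (np.abs(res.t[_mask((V, 1, 1))]) > crit).mean()
        assert abs(frac - 0.05) < 0.015

    def test_rank_deficient_design_rejected(self, rng):
        maps = rng.normal(0, 1, (10, 2, 2, 2))
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(StatsError):
            voxel_glm(maps, X, [0, 1], _mask((2, 2, 2)))

    def test_residuals_orthogonal_to_design(self, rng):
        n = 30
        maps = rng.normal(0, 1, (n, 4, 4, 2))
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        res = voxel_glm(maps, X, [0, 1], _mask((4, 4, 2)))
        resid = res.residuals.reshape(n, -1)
        assert np.abs(X.T @ resid).max() < 1e-8


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        assert t_to_z(np.zeros((2, 2, 2)), 30).max() == 0.0

    def test_large_df_limit_approaches_identity(self):
        z = t_to_z(np.array([2.0]), 10000)
        assert abs(z[0] - 2.0) < 0.01

    def test_matches_high_precision_evaluation(self):
        # Phi^-1(F_t(2.5; 60)) computed via the log survival function
        z = t_to_z(np.array([2.5]), 60)
        assert abs(z[0] - 2.428276312542084) < 1e-9

    def test_monotone_and_sign_preserving(self):
        t = np.linspace(-8, 8, 33)
        z = t_to_z(t, 25)
        assert (np.diff(z) > 0).all()
        assert np.allclose(np.sign(z), np.sign(t))

    def test_tail_safe_for_extreme_t(self):
        z = t_to_z(np.array([-80.0, 80.0]), 50)
        assert np.isfinite(z).all() and z[1] > 10 and z[0] < -10


class TestSmoothZ:
    def test_constant_field_unchanged(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        out = smooth_z(np.where(mask, 3.0, 0.0), 4.0, mask)
        assert np.allclose(out[mask], 3.0)

    def test_kernel_sd_matches_sigma_over_voxel_size(self, rng):
        # away from mask edges the mask-normalized filter equals a plain
        # Gaussian filter with sd = 4 mm / 3 mm voxels
        field = rng.normal(0, 1, (24, 24, 24))
        mask = np.ones((24, 24, 24), bool)
        out = smooth_z(field, 4.0, mask, voxel_mm=3.0)
        ref = ndimage.gaussian_filter(field, 4.0 / 3.0)
        center = (slice(8, 16),) * 3
        assert np.abs(out[center] - ref[center]).max() < 1e-6

    def test_spike_spreads_with_distance_decay(self):
        field = np.zeros((15, 15, 15))
        field[7, 7, 7] = 10.0
        out = smooth_z(field, 4.0, _mask((15, 15, 15)))
        assert out[7, 7, 7] > out[7, 7, 9] > out[7, 7, 11] > 0

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(StatsError):
            smooth_z(np.zeros((4, 4, 4)), 0.0, _mask((4, 4, 4)))


class TestSmoothness:
    def test_white_noise_reports_voxel_floor(self, rng):
        maps = rng.normal(0, 1, (8, 20, 20, 20))
        f = estimate_smoothness(maps, _mask((20, 20, 20)), voxel_mm=3.0)
        assert np.allclose(f, 3.0, rtol=0.15)

    def test_smoothed_noise_recovers_kernel_width(self, rng):
        sigma_vox = 4.0 / 3.0
        maps = np.stack([ndimage.gaussian_filter(rng.normal(0, 1, (30, 30, 30)),
                                                 sigma_vox) for _ in range(6)])
        f = estimate_smoothness(maps, _mask((30, 30, 30)), voxel_mm=3.0)
        target = 2.3548 * 4.0  # FWHM of the smoothing kernel in mm
        assert np.allclose(f, target, rtol=0.15)

    def test_invariant_to_residual_rescaling(self, rng):
        maps = np.stack([ndimage.gaussian_filter(rng.normal(0, 1, (20, 20, 20)), 1.0)
                         for _ in range(4)])
        f1 = estimate_smoothness(maps, _mask((20, 20, 20)))
        f2 = estimate_smoothness(maps * 57.0, _mask((20, 20, 20)))
        assert np.allclose(f1, f2)

    def test_constant_residuals_rejected(self):
        with pytest.raises(StatsError):
            estimate_smoothness(np.ones((3, 8, 8, 8)), _mask((8, 8, 8)))


class TestClusters:
    def test_empty_field_gives_empty_set(self):
        cs = extract_clusters(np.zeros((8, 8, 8)), 2.5, 5)
        assert len(cs) == 0

    def test_block_extent_boundary(self):
        z = np.zeros((9, 9, 9))
        z[3:6, 3:6, 3:6] = 3.0
        assert len(extract_clusters(z, 2.5, 27)) == 1
        assert extract_clusters(z, 2.5, 27).clusters[0].size == 27
        assert len(extract_clusters(z, 2.5, 28)) == 0

    def test_negative_tail_symmetric(self):
        z = np.zeros((9, 9, 9))
        z[3:6, 3:6, 3:6] = -3.0
        assert len(extract_clusters(z, 2.5, 27, two_sided=False)) == 0
        cs = extract_clusters(z, 2.5, 27, two_sided=True)
        assert len(cs) == 1 and cs.clusters[0].sign == -1
        assert cs.clusters[0].peak_z == -3.0

    def test_connectivity_rules_differ_on_diagonal_touch(self):
        z = np.zeros((6, 6, 6))
        z[1, 1, 1] = z[2, 2, 2] = 3.0  # touch only at a corner
        assert len(extract_clusters(z, 2.5, 2, connectivity=26)) == 1
        assert len(extract_clusters(z, 2.5, 2, connectivity=6)) == 0

    def test_agrees_with_flood_fill_oracle(self, rng):
        z = rng.normal(0, 1, (12, 12, 12))
        cs = extract_clusters(z, 1.5, 1, connectivity=26)
        # brute-force flood fill
        supra = z > 1.5
        seen = np.zeros_like(supra)
        sizes = []
        offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                   for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
        for start in np.argwhere(supra):
            if seen[tuple(start)]:
                continue
            stack, comp = [tuple(start)], 0
            seen[tuple(start)] = True
            while stack:
                cur = stack.pop()
                comp += 1
                for off in offsets:
                    nb = tuple(np.add(cur, off))
                    if all(0 <= nb[d] < 12 for d in range(3)) and supra[nb] and not seen[nb]:
                        seen[nb] = True
                        stack.append(nb)
            sizes.append(comp)
        assert sorted(c.size for c in cs.clusters) == sorted(sizes)


class TestCalibration:
    def test_unreachable_threshold_gives_zero_alpha(self):
        mask = np.ones((16, 16, 16), bool)
        cal = calibrate_cluster_threshold(mask, 3.0, 40.0, n_sims=100, seed=0)
        assert (cal.alpha == 0).all()

    def test_alpha_monotone_in_extent(self):
        mask = np.ones((20, 20, 20), bool)
        cal = calibrate_cluster_threshold(mask, 3.0, 2.0, n_sims=150, seed=1,
                                          exogenous_sigma_mm=4.0)
        assert (np.diff(cal.alpha) <= 0).all()
        assert cal.alpha_at(1) >= cal.alpha_at(100)

    def test_too_few_sims_rejected(self):
        with pytest.raises(StatsError):
            calibrate_cluster_threshold(np.ones((8, 8, 8), bool), 3.0, 2.5,
                                        n_sims=10, seed=0)


class TestBuildDesign:
    def test_contrast_selects_predictor(self):
        import pandas as pd
        tab = pd.DataFrame({"group": [0, 1, 0], "age": [10., 12., 14.],
                            "gender": [0, 1, 1]})
        X, c = build_design(tab, "group", ["age", "gender"])
        assert X.shape == (3, 4)
        assert c.tolist() == [0, 1, 0, 0]
        assert np.array_equal(X[:, 1], [0, 1, 0])
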