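"""Evaluation metrics: closed-form cases, independent oracles, and the
invariance/stability harnesses."""

import itertools

import numpy as np
import pytest

from refocus.metrics import (GAUSS_FWHM, bead_fwhm, histogram_kl, nrmse,
                             permutation_stats, psnr, roi_rmse,
                             stability_sweep)
from refocus.stack import ImagePlane, ImageStack


class TestNrmsePsnr:
    def test_identical_images(self, rng):
        x = rng.uniform(size=(16, 16))
        assert nrmse(x, x) == 0.0
        assert psnr(x, x) == np.inf

    def test_constant_offset_closed_form(self, rng):
        # unit-range reference, +0.1 offset: MSE = 0.01, PSNR = 20 dB,
        # NRMSE = 10%
        y = rng.uniform(size=(32, 32))
        y = (y - y.min()) / np.ptp(y)          # exact unit range
        x = y + 0.1
        assert psnr(x, y) == pytest.approx(20.0, abs=1e-9)
        assert nrmse(x, y) == pytest.approx(10.0, abs=1e-9)

    def test_nrmse_symmetric_for_equal_ranges(self, rng):
        y = rng.uniform(size=(16, 16))
        x = y[::-1].copy()                      # same value set, same range
        assert nrmse(x, y) == pytest.approx(nrmse(y, x))

    def test_affine_invariance_of_range_normalized_metrics(self, rng):
        x = rng.uniform(size=(16, 16))
        y = rng.uniform(size=(16, 16))
        a, b = 3.7, -12.0
        assert nrmse(a * x + b, a * y + b) == pytest.approx(nrmse(x, y))
        assert psnr(a * x + b, a * y + b) == pytest.approx(psnr(x, y))

    def test_zero_range_rejected(self, rng):
        with pytest.raises(ValueError):
            nrmse(rng.uniform(size=(8, 8)), np.ones((8, 8)))


class TestRoiRmse:
    def test_identical_rois(self, rng):
        x = rng.uniform(0, 255, size=(16, 16))
        assert roi_rmse(x, x, (slice(2, 6), slice(2, 6))) == 0.0

    def test_four_pixel_hand_case(self):
        # display-scale differences (0, 0, 0, 2) -> RMSE = 1
        y = np.zeros((2, 2))
        y[0, 0] = 255.0                         # fixes the display mapping
        x = y.copy()
        x[1, 1] += 2.0
        assert roi_rmse(x, y) == pytest.approx(1.0)

    def test_full_image_equals_plain_rmse_on_display_scale(self, rng):
        y = rng.uniform(0, 255, size=(16, 16))
        y[0, 0], y[1, 1] = 0.0, 255.0           # identity display mapping
        x = y + rng.normal(size=y.shape)
        expected = np.sqrt(np.mean((x - y) ** 2))
        assert roi_rmse(x, y) == pytest.approx(expected)

    def test_empty_roi_rejected(self, rng):
        x = rng.uniform(size=(8, 8))
        with pytest.raises(ValueError):
            roi_rmse(x, x, np.zeros((8, 8), dtype=bool))


def _plant_gaussians(centres, sigmas, size=96, amp=100.0):
    img = np.zeros((size, size))
    yy, xx = np.mgrid[:size, :size]
    for (r, c), s in zip(centres, sigmas):
        img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * s * s))
    return img


class TestBeadFwhm:
    def test_planted_sigma_recovered(self):
        img = _plant_gaussians([(48, 48)], [2.0])
        rep = bead_fwhm(img, pixel_size=0.1)
        assert rep.n_beads == 1
        assert rep.mean_fwhm_um == pytest.approx(GAUSS_FWHM * 2.0 * 0.1,
                                                 rel=0.05)

    def test_exclusion_radius_brute_force(self):
        # three beads; the close pair is rejected, the isolated one kept
        centres = [(20, 20), (20, 26), (70, 70)]
        img = _plant_gaussians(centres, [1.5] * 3)
        rep = bead_fwhm(img, pixel_size=0.1, exclusion_radius_px=10.0)
        # oracle: pairwise distances
        d = {(i, j): np.hypot(centres[i][0] - centres[j][0],
                              centres[i][1] - centres[j][1])
             for i, j in itertools.combinations(range(3), 2)}
        assert d[(0, 1)] < 10.0 < d[(0, 2)]
        assert rep.n_beads == 1

    def test_fwhm_scales_linearly_with_sigma(self):
        fwhms, sigmas = [], [1.0, 2.0, 3.0]
        for s in sigmas:
            rep = bead_fwhm(_plant_gaussians([(48, 48)], [s]), pixel_size=1.0)
            fwhms.append(rep.mean_fwhm_um)
        slope, intercept = np.polyfit(sigmas, fwhms, 1)
        resid = np.array(fwhms) - (slope * np.array(sigmas) + intercept)
        r2 = 1 - resid.var() / np.var(fwhms)
        assert r2 > 0.99
        assert slope == pytest.approx(GAUSS_FWHM, rel=0.05)

    def test_no_beads_warns_empty_report(self):
        with pytest.warns(UserWarning):
            rep = bead_fwhm(np.zeros((32, 32)) + 1.0, pixel_size=0.1)
        assert rep.n_beads == 0


class TestHistogramKl:
    def test_identical_histograms(self):
        h = np.array([5, 3, 2, 7])
        assert histogram_kl(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        # 0.5 ln(0.5/0.9) + 0.5 ln(0.5/0.1) ~ 0.5108
        val = histogram_kl(np.array([0.5, 0.5]), np.array([0.9, 0.1]))
        expected = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert val == pytest.approx(expected, abs=1e-3)

    def test_gibbs_nonnegativity(self, rng):
        for _ in range(20):
            p = rng.uniform(0.01, 1, size=10)
            q = rng.uniform(0.01, 1, size=10)
            assert histogram_kl(p, q) >= 0

    def test_smoothing_insensitivity_on_populated_histograms(self, rng):
        p = rng.uniform(0.1, 1, size=20)
        q = rng.uniform(0.1, 1, size=20)
        a = histogram_kl(p, q, eps=1e-4)
        b = histogram_kl(p, q, eps=1e-5)
        assert abs(a - b) / a < 0.01

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            histogram_kl(np.ones(5), np.ones(6))


def _gt_stack(rng, n=3, size=32):
    return ImageStack.from_array(rng.uniform(size=(n, size, size)),
                                 np.arange(n, dtype=float))


def _planes(zs, size=32, seed=0):
    rng = np.random.default_rng(seed)
    return [ImagePlane(rng.uniform(size=(size, size)), float(z)) for z in zs]


class TestPermutationStats:
    def test_permutation_blind_stub_gives_zero_sigma(self, rng):
        gt = _gt_stack(rng)
        const = rng.uniform(size=(3, 32, 32))
        stub = lambda planes, z_grid: ImageStack.from_array(
            const, np.asarray(z_grid))
        stats = permutation_stats(stub, _planes([0.0, 1.0, 2.0]),
                                  [0.0, 1.0, 2.0], gt)
        assert stats.n_permutations == 6
        # zero up to the floating error of the mean over identical values
        np.testing.assert_allclose(stats.sigma_rmse, 0.0, atol=1e-12)
        np.testing.assert_allclose(stats.sd_map, 0.0, atol=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        from refocus.metrics import roi_rmse as _rr
        gt = _gt_stack(rng)
        planes = _planes([0.0, 1.0, 2.0], seed=3)

        def order_sensitive(pl, z_grid):
            # weights depend on position in the sequence
            vol = np.stack([
                sum((i + 1) * p.pixels * (1 + z) for i, p in enumerate(pl))
                for z in z_grid])
            return ImageStack.from_array(vol, np.asarray(z_grid))

        stats = permutation_stats(order_sensitive, planes, [0.0, 1.0, 2.0],
                                  gt)
        # independent loop over an explicitly enumerated permutation list
        perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1),
                 (2, 1, 0)]
        all_rmse = np.empty((6, 3))
        for pi, perm in enumerate(perms):
            vol = order_sensitive([planes[i] for i in perm],
                                  [0.0, 1.0, 2.0]).as_array()
            for zi in range(3):
                all_rmse[pi, zi] = _rr(vol[zi], gt.as_array()[zi])
        mu = all_rmse.mean(axis=0)
        sigma = np.sqrt(np.mean((all_rmse - mu) ** 2, axis=0))
        np.testing.assert_allclose(stats.mu_rmse, mu, atol=1e-10)
        np.testing.assert_allclose(stats.sigma_rmse, sigma, atol=1e-10)
        assert stats.sigma_rmse.max() > 0

    def test_factorial_cap(self, rng):
        gt = _gt_stack(rng)
        stub = lambda planes, z_grid: gt
        with pytest.raises(ValueError, match="permutations"):
            permutation_stats(stub, _planes(range(6)), [0.0, 1.0, 2.0], gt,
                              max_permutations=100)


class TestStabilitySweep:
    def test_sigma_zero_is_bit_exact_baseline(self, tiny_model, rng):
        gt = _gt_stack(rng)
        planes = _planes([0.0, 1.0, 2.0], seed=4)
        from refocus.reconstruct import infer_volume
        baseline = infer_volume(tiny_model, planes, gt.z_grid).as_array()
        df = stability_sweep(tiny_model, planes, gt.z_grid, gt, sigmas=[0.0],
                             n_trials=3, seed=0)
        base_nrmse = [nrmse(baseline[i], gt.as_array()[i]) for i in range(3)]
        for trial in range(3):
            sub = df[df.trial == trial].sort_values("z")
            np.testing.assert_array_equal(sub["nrmse"].to_numpy(), base_nrmse)

    def test_default_trial_count_matches_protocol(self):
        import inspect
        sig = inspect.signature(stability_sweep)
        assert sig.parameters["n_trials"].default == 50

    def test_noise_changes_reconstruction(self, tiny_model, rng):
        gt = _gt_stack(rng)
        planes = _planes([0.0, 1.0, 2.0], seed=4)
        df = stability_sweep(tiny_model, planes, gt.z_grid, gt,
                             sigmas=[0.0, 1.0], n_trials=2, seed=1)
        v0 = df[df.sigma == 0.0]["nrmse"].to_numpy()
        v1 = df[df.sigma == 1.0]["nrmse"].to_numpy()
        assert not np.allclose(v0, v1)

    def test_negative_sigma_rejected(self, tiny_model, rng):
        gt = _gt_stack(rng)
        with pytest.raises(ValueError):
            stability_sweep(tiny_model, _planes([0.0, 1.0]), gt.z_grid, gt,
                            sigmas=[-0.5], n_trials=1)
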