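import numpy as np
import pytest
from scipy.integrate import quad

from ebcometkit.comet_fit import (
    CometProfile,
    N_HORDES,
    ProfileError,
    build_comet_profile,
    exp_gauss,
    extract_polar_profiles,
    fit_profile,
    simulate_profile,
    tip_global_coords,
)
from ebcometkit.growth_sim import _render_comet_frame


X_GRID = np.arange(-10.0, 30.0001, 0.1)


class TestExpGauss:
    def test_matches_independent_quadrature(self):
        # oracle: direct numerical convolution of the one-sided exponential
        # with the Gaussian kernel, normalised by d*sqrt(pi)
        x_c, L, d = -2.0, 8.0, 1.5

        def oracle(x):
            val, _ = quad(
                lambda u: np.exp(-(u - x_c) / L) * np.exp(-((x - u) ** 2) / d**2),
                x_c,
                x_c + 40 * L,
                limit=400,
            )
            return val / (d * np.sqrt(np.pi))

        xs = np.array([-4.0, -1.0, 0.0, 1.3, 5.0, 12.0, 25.0])
        ours = exp_gauss(xs, x_c, L, d)
        theirs = np.array([oracle(x) for x in xs])
        np.testing.assert_allclose(ours, theirs, atol=1e-8, rtol=1e-8)

    def test_delta_kernel_limit_recovers_exponential(self):
        # as d -> 0 the convolution collapses onto the bare exponential
        x = X_GRID[X_GRID > -2.0 + 0.3]
        model = exp_gauss(x, -2.0, 12.0, 0.05)
        expected = np.exp(-(x + 2.0) / 12.0)
        np.testing.assert_allclose(model, expected, rtol=0.01)

    def test_monotone_decay_beyond_maximum(self):
        y = exp_gauss(X_GRID, -3.0, 10.0, 2.0)
        peak = np.argmax(y)
        assert np.all(np.diff(y[peak:]) <= 1e-12)

    def test_translation_covariance(self):
        delta = 1.7
        a = exp_gauss(X_GRID, -2.0, 9.0, 1.5)
        b = exp_gauss(X_GRID + delta, -2.0 + delta, 9.0, 1.5)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            exp_gauss(X_GRID, 0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            exp_gauss(X_GRID, 0.0, 1.0, 0.0)


class TestSimulateProfile:
    def test_threshold_clips_at_zero(self):
        y = simulate_profile((0.5, -2.0, 1.5, 8.0, 1.0), X_GRID)
        assert y.min() == 0.0
        assert (y == 0).any()

    def test_amplitude_scales_linearly_above_zero_threshold(self):
        y1 = simulate_profile((0.0, -2.0, 1.5, 8.0, 1.0), X_GRID)
        y2 = simulate_profile((0.0, -2.0, 1.5, 8.0, 3.0), X_GRID)
        np.testing.assert_allclose(y2, 3.0 * y1, rtol=1e-12)


class TestFitProfile:
    @pytest.mark.parametrize("L,d,x_c", [(4.0, 1.0, 0.0), (12.0, 2.0, -3.0), (20.0, 3.0, -5.0)])
    def test_noiseless_recovery_exact(self, L, d, x_c):
        true = (0.02, x_c, d, L, 1.0)
        y = simulate_profile(true, X_GRID)
        fit = fit_profile(CometProfile(x=X_GRID, intensity=y))
        assert fit.L == pytest.approx(L, rel=0.02)
        assert fit.x_c == pytest.approx(x_c, abs=0.1)
        assert fit.d == pytest.approx(d, rel=0.02)

    def test_zero_tip_shift_recovered(self):
        y = simulate_profile((0.01, 0.0, 1.5, 10.0, 1.0), X_GRID)
        fit = fit_profile(CometProfile(x=X_GRID, intensity=y))
        assert abs(fit.x_c) < 0.1

    def test_residual_not_worse_than_truth(self, rng):
        true = (0.02, -2.5, 1.8, 9.0, 1.0)
        y = simulate_profile(true, X_GRID)
        fit = fit_profile(CometProfile(x=X_GRID, intensity=y))
        truth_res = float(np.sum((simulate_profile(true, X_GRID) - y) ** 2))
        assert fit.residual <= truth_res + 1e-12

    def test_length_invariant_under_amplitude_rescaling(self):
        y = simulate_profile((0.0, -2.0, 1.5, 11.0, 1.0), X_GRID)
        f1 = fit_profile(CometProfile(x=X_GRID, intensity=y))
        f2 = fit_profile(CometProfile(x=X_GRID, intensity=250.0 * y))
        assert f2.L == pytest.approx(f1.L, rel=1e-3)

    def test_flat_profile_rejected(self):
        with pytest.raises(ProfileError):
            fit_profile(CometProfile(x=X_GRID, intensity=np.ones_like(X_GRID)))

    def test_too_few_positive_samples_rejected(self):
        y = np.zeros_like(X_GRID)
        y[:10] = 1.0
        with pytest.raises(ProfileError):
            fit_profile(CometProfile(x=X_GRID, intensity=y))

    def test_t_bounds_constrain_threshold(self):
        y = simulate_profile((0.3, -2.0, 1.5, 10.0, 1.0), X_GRID)
        fit = fit_profile(CometProfile(x=X_GRID, intensity=y), t_bounds=(0.25, 0.35))
        assert 0.25 <= fit.T <= 0.35


class TestPolarExtraction:
    def test_radially_symmetric_blob_flagged_low_anisotropy(self):
        frame = np.zeros((80, 80))
        yy, xx = np.mgrid[0:80, 0:80]
        frame += 10 * np.exp(-((yy - 40.0) ** 2 + (xx - 40.0) ** 2) / 8.0)
        hordes = extract_polar_profiles(frame, (40, 40), r_max=20.0)
        integrals = hordes.profiles.sum(axis=1)
        assert np.ptp(integrals) < 0.01 * integrals.mean()
        assert hordes.low_anisotropy

    def test_horde_step_is_5_625_degrees(self):
        frame = np.ones((64, 64))
        hordes = extract_polar_profiles(frame, (32, 32), r_max=12.0)
        steps = np.diff(hordes.angles)
        np.testing.assert_allclose(np.degrees(steps), 5.625, rtol=1e-12)
        assert len(hordes.angles) == N_HORDES

    def test_tail_points_along_rendered_tail(self):
        # comet tail pointing at 90 deg (down the rows) -> tail horde 16
        frame = np.zeros((120, 120))
        _render_comet_frame(frame, (60.0, 40.0), np.pi * 3 / 2, 10.0, 100.0, 1.5)
        iy, ix = np.unravel_index(np.argmax(frame), frame.shape)
        hordes = extract_polar_profiles(frame, (ix, iy), r_max=30.0)
        assert hordes.tail_index == 16
        assert hordes.head_index == 48
        assert not hordes.low_anisotropy

    def test_tail_prior_restricts_search(self):
        frame = np.zeros((120, 120))
        _render_comet_frame(frame, (60.0, 60.0), 0.0, 10.0, 100.0, 1.5)
        iy, ix = np.unravel_index(np.argmax(frame), frame.shape)
        # prior pointing opposite the true tail forbids the real direction
        hordes = extract_polar_profiles(
            frame, (ix, iy), r_max=30.0, tail_prior_rad=0.0,
            tail_prior_halfwidth_rad=0.5,
        )
        assert abs(np.angle(np.exp(1j * (hordes.phi_tail - 0.0)))) <= 0.5

    def test_border_center_flagged_invalid(self):
        frame = np.ones((40, 40))
        hordes = extract_polar_profiles(frame, (3, 3), r_max=30.0, r_min=10.0)
        assert not hordes.valid
        with pytest.raises(ProfileError):
            build_comet_profile(hordes)


class TestTipGlobalCoords:
    def _hordes(self, phi_head):
        from ebcometkit.comet_fit import HordeSet

        angles = np.arange(64) * (2 * np.pi / 64)
        idx = int(round(phi_head / (2 * np.pi / 64)))
        return HordeSet(
            x_max=100.0, y_max=50.0, angles=angles, radii=np.arange(5.0),
            profiles=np.zeros((64, 5)), tail_index=(idx + 32) % 64,
        )

    def _fit(self, x_c):
        from ebcometkit.comet_fit import CometFit

        return CometFit(T=0, x_c=x_c, d=1.5, L=10, A=1, residual=0,
                        clipped_fraction=0, converged=True)

    def test_zero_shift_keeps_brightest_pixel(self):
        tip = tip_global_coords(self._fit(0.0), self._hordes(0.0))
        assert (tip.x_end, tip.y_end) == (100.0, 50.0)

    def test_shift_along_x_axis(self):
        tip = tip_global_coords(self._fit(10.0), self._hordes(0.0))
        assert tip.x_end == pytest.approx(110.0)
        assert tip.y_end == pytest.approx(50.0)

    def test_shift_along_y_axis_only(self):
        tip = tip_global_coords(self._fit(-3.0), self._hordes(np.pi / 2))
        assert tip.x_end == pytest.approx(100.0, abs=1e-9)
        assert tip.y_end == pytest.approx(53.0)

    def test_nm_conversion(self):
        tip = tip_global_coords(self._fit(0.0), self._hordes(0.0), pixel_size_nm=103.0)
        assert tip.x_end_nm == pytest.approx(10300.0)


class TestParameterRecoveryStatistics:
    def test_noiseless_grid_within_2_percent(self, rng):
        errs = []
        for _ in range(40):
            L = rng.uniform(4, 20)
            d = rng.uniform(1, 3)
            x_c = rng.uniform(-5, 0)
            y = simulate_profile((0.02, x_c, d, L, 1.0), X_GRID)
            fit = fit_profile(CometProfile(x=X_GRID, intensity=y))
            errs.append(abs(fit.L - L) / L)
        assert np.median(errs) < 0.02

    def test_snr10_median_under_15_percent(self, rng):
        errs = []
        for _ in range(60):
            L = rng.uniform(4, 20)
            d = rng.uniform(1, 3)
            x_c = rng.uniform(-5, 0)
            y = simulate_profile((0.02, x_c, d, L, 1.0), X_GRID)
            noisy = np.maximum(y + rng.normal(0, y.max() / 10, y.shape), 0)
            fit = fit_profile(CometProfile(x=X_GRID, intensity=noisy))
            errs.append(abs(fit.L - L) / L)
        assert np.median(errs) < 0.15
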