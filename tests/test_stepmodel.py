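"""Forward-model algebra, damping, staged fit and the sigma landscape."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrilsaxs import (
    StepDensityParams,
    damping,
    fit_profile,
    forward_intensity,
    generate_saxs_profile,
    interference_term,
    sigma_landscape,
)
from fibrilsaxs.stepmodel import (
    detect_bragg_peaks,
    estimate_initial_params,
    fluctuation_term,
    monotone_term,
)
from conftest import fourier_intensity_at, sampled_step_density


class TestInterference:
    @pytest.mark.parametrize("n", [1, 2, 3, 7])
    @pytest.mark.parametrize("N", [2, 5, 10])
    def test_bragg_limit_is_N_squared(self, n, N):
        q = np.array([2.0 * np.pi * n / 65.5])
        assert interference_term(q, 65.5, N) == pytest.approx(N**2)

    def test_single_period_is_unity(self, saxs_q):
        assert np.allclose(interference_term(saxs_q, 65.5, 1), 1.0)

    @given(st.floats(0.06, 1.2), st.integers(2, 20), st.floats(50.0, 80.0))
    @settings(max_examples=60, deadline=None)
    def test_matches_geometric_sum(self, q, N, D):
        """S_N(q) equals |sum_k exp(i q k D)|^2 computed directly."""
        direct = abs(sum(np.exp(1j * q * k * D) for k in range(N))) ** 2
        assert interference_term(np.array([q]), D, N)[0] == pytest.approx(
            direct, rel=1e-9, abs=1e-9)

    def test_midway_between_orders_is_small(self):
        q = np.array([2.0 * np.pi * 3.5 / 65.5])
        assert interference_term(q, 65.5, 10)[0] < 1.0

    @pytest.mark.parametrize("N", [5, 10, 20])
    def test_peak_width_scales_inversely_with_N(self, N):
        """FWHM in q of the grating peak decreases as 1/N."""
        D = 65.5
        q3 = 2.0 * np.pi * 3 / D
        dq = np.linspace(-0.05, 0.05, 4001)
        curve = interference_term(q3 + dq, D, N)
        half = curve >= N**2 / 2.0
        fwhm = dq[half][-1] - dq[half][0]
        assert fwhm == pytest.approx(5.566 / (N * D), rel=0.05)


class TestDiffraction:
    def test_even_orders_vanish_at_symmetric_density(self):
        """sigma = 0.5: the fluctuation term is zero at even Bragg orders."""
        n = np.array([2, 4, 6, 8])
        q = 2.0 * np.pi * n / 65.5
        assert np.allclose(fluctuation_term(q, 65.5, 0.5, 0.08), 0.0, atol=1e-25)

    def test_zero_contrast_leaves_pure_monotone(self, saxs_q):
        p = StepDensityParams(D=65.5, N=10, sigma=0.46, delta_rho=0.0)
        assert np.allclose(forward_intensity(saxs_q, p),
                           monotone_term(saxs_q, 1.0))

    def test_bragg_weights_match_fourier_oracle(self):
        """Fluctuation weights at orders 1..9 equal sin^2(pi n sigma)/n^2
        (up to a common factor), cross-checked against a direct Fourier
        transform of the sampled one-period step density."""
        sigma, D, drho = 0.46, 65.5, 0.08
        p = StepDensityParams(D=D, N=1, sigma=sigma, rho_ave=0.0, delta_rho=drho)
        z, rho = sampled_step_density(p)
        n = np.arange(1, 10)
        q_n = 2.0 * np.pi * n / D
        oracle = fourier_intensity_at(z, rho, q_n)
        model = fluctuation_term(q_n, D, sigma, drho)
        scale = np.dot(oracle, model) / np.dot(model, model)
        np.testing.assert_allclose(scale * model, oracle, rtol=1e-2)
        # and the closed-form reduction at the Bragg condition
        closed = 4.0 * drho**2 / q_n**2 * np.sin(np.pi * n * sigma) ** 2
        np.testing.assert_allclose(model, closed, rtol=1e-12)

    def test_q_zero_rejected(self):
        with pytest.raises(ValueError):
            monotone_term(np.array([0.0, 0.1]), 1.0)


class TestDamping:
    def test_disabled_forms_are_unity(self, saxs_q):
        assert np.allclose(damping(saxs_q, 0.0, 0.0), 1.0)
        assert np.allclose(damping(saxs_q, 9.0, 1.0), 1.0)

    def test_high_q_floor(self):
        w, c = 9.0, 0.05
        q = np.array([20.0 * 2.0 * np.pi / w])
        assert damping(q, w, c)[0] == pytest.approx(c, abs=0.01)

    def test_monotone_nonincreasing_and_bounded(self, saxs_q):
        d = damping(saxs_q, 9.0, 0.05)
        assert np.all(np.diff(d) <= 0)
        assert np.all((d > 0) & (d <= 1.0))
        assert damping(np.array([1e-12]), 9.0, 0.05)[0] == pytest.approx(1.0)


class TestForwardModel:
    def test_nonnegative_everywhere(self, control_profile):
        assert np.all(control_profile.intensity >= 0)

    def test_local_maxima_at_bragg_positions(self, control_profile, control_truth):
        """Orders 3,5,6,7,9 appear as local maxima at q_n = 2 pi n / D."""
        q = control_profile.q
        y = control_profile.intensity
        D = control_truth.step_params.D
        fwhm = 5.566 / (10 * D)
        for n in (3, 5, 6, 7, 9):
            qn = 2.0 * np.pi * n / D
            window = (q > qn - 0.5 * fwhm) & (q < qn + 0.5 * fwhm)
            i_max = np.argmax(y[window])
            q_max = q[window][i_max]
            assert abs(q_max - qn) <= 0.5 * fwhm

    def test_even_order_suppression_ordering(self, control_truth):
        """At sigma = 0.46 the 4th order is weaker than the 3rd and 5th."""
        p = control_truth.step_params
        q_n = p.bragg_q(np.array([3, 4, 5]))
        structured = (damping(q_n, p.w, p.c)
                      * fluctuation_term(q_n, p.D, p.sigma, p.delta_rho)
                      * interference_term(q_n, p.D, p.N))
        assert structured[1] < structured[0]
        assert structured[1] < structured[2]

    def test_structured_part_matches_multi_period_fourier_oracle(self):
        """Undamped fluctuation x interference agrees with |Fourier
        transform of the sampled N-period mean-subtracted step density|^2
        at the Bragg positions within 1%, after matching overall scale."""
        for D in (64.0, 67.0):
            for sigma in (0.44, 0.48):
                p = StepDensityParams(D=D, N=10, sigma=sigma,
                                      rho_ave=0.0, delta_rho=0.08)
                z, rho = sampled_step_density(p, oversample=2**14)
                n = np.array([1, 3, 5, 7, 9])
                q_n = 2.0 * np.pi * n / D
                oracle = fourier_intensity_at(z, rho, q_n)
                model = (fluctuation_term(q_n, D, sigma, 0.08)
                         * interference_term(q_n, D, 10))
                scale = np.dot(oracle, model) / np.dot(model, model)
                np.testing.assert_allclose(scale * model, oracle, rtol=1e-2)

    def test_empty_q_rejected(self, control_truth):
        with pytest.raises(ValueError):
            forward_intensity(np.array([]), control_truth.step_params)


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        dict(D=-1.0), dict(N=0), dict(sigma=0.0), dict(sigma=1.0),
        dict(delta_rho=-0.1), dict(w=-1.0), dict(c=1.5),
    ])
    def test_invalid_params_rejected(self, kw):
        base = dict(D=65.5, N=10, sigma=0.46)
        base.update(kw)
        with pytest.raises(ValueError):
            StepDensityParams(**base)


class TestFit:
    def test_noiseless_recovery(self, control_profile, control_truth):
        """Self-consistency: the fit recovers the generating parameters
        within one refinement grid step."""
        fit = fit_profile(control_profile)
        p = control_truth.step_params
        assert abs(fit.params.D - p.D) <= 0.1
        assert abs(fit.params.sigma - p.sigma) <= 0.002
        assert abs(fit.params.delta_rho - p.delta_rho) / p.delta_rho <= 0.05
        assert fit.params.N == p.N
        assert fit.r_squared > 0.99
        assert fit.converged

    def test_iteration_cap(self, control_profile):
        fit = fit_profile(control_profile)
        assert 1 <= fit.n_iterations <= 10

    def test_initialization_from_data(self, control_profile, control_truth):
        init = estimate_initial_params(control_profile)
        assert abs(init.D - control_truth.step_params.D) < 0.5
        assert init.sigma == 0.46
        assert init.delta_rho == 0.0 and init.w == 0.0 and init.c == 0.0

    def test_pure_background_gives_zero_contrast(self, saxs_q, control_truth):
        """A 1/q^2 curve without Bragg structure fits with delta_rho ~ 0 and
        a flat sigma landscape."""
        flat_truth = control_truth.replace(
            step_params=control_truth.step_params.replace(delta_rho=0.0))
        profile = generate_saxs_profile(flat_truth, saxs_q, noise="none")
        init = flat_truth.step_params.replace(delta_rho=0.0, w=0.0, c=0.0)
        fit = fit_profile(profile, init=init, fit_range=(0.25, 1.2))
        assert fit.params.delta_rho <= 0.005
        rmse = sigma_landscape(profile, fit, np.linspace(0.3, 0.7, 21))
        assert np.ptp(rmse) <= 1e-6 * np.mean(profile.intensity)

    def test_insufficient_orders_raises(self, saxs_q, control_truth):
        flat_truth = control_truth.replace(
            step_params=control_truth.step_params.replace(delta_rho=0.0))
        profile = generate_saxs_profile(flat_truth, saxs_q, noise="none")
        with pytest.raises(ValueError, match="[Ii]nsufficient|orders|peaks"):
            fit_profile(profile)

    def test_r_squared_improves_without_noise(self, control_truth, saxs_q):
        """R^2 under the defining variance ratio is higher on noiseless data
        than on the same truth with counting noise."""
        clean = generate_saxs_profile(control_truth, saxs_q, noise="none")
        noisy = generate_saxs_profile(control_truth.replace(seed=4), saxs_q,
                                      noise="poisson")
        r2_clean = fit_profile(clean).r_squared
        r2_noisy = fit_profile(noisy).r_squared
        assert 0.0 <= r2_noisy <= r2_clean <= 1.0


class TestSigmaLandscape:
    def test_minimum_at_planted_gap_fraction(self, control_truth, saxs_q):
        truth = control_truth.replace(
            step_params=control_truth.step_params.replace(sigma=0.475))
        profile = generate_saxs_profile(truth, saxs_q, noise="none")
        fit = fit_profile(profile)
        sig = np.linspace(0.30, 0.70, 81)  # 0.005 grid
        rmse = sigma_landscape(profile, fit, sig)
        gap_min = 1.0 - sig[np.argmin(rmse)]
        # Babinet degeneracy: the planted gap fraction and its complement
        # are indistinguishable, so either minimum is correct
        assert min(abs(gap_min - 0.525), abs(gap_min - 0.475)) <= 0.005

    def test_babinet_symmetry(self, control_profile):
        """RMSE(sigma) = RMSE(1 - sigma): complementary densities scatter
        identically at the Bragg orders."""
        fit = fit_profile(control_profile)
        sig = np.linspace(0.35, 0.65, 31)
        rmse = sigma_landscape(control_profile, fit, sig)
        np.testing.assert_allclose(rmse, rmse[::-1], rtol=1e-6)

    def test_sigma_grid_bounds_checked(self, control_profile):
        fit = fit_profile(control_profile)
        with pytest.raises(ValueError):
            sigma_landscape(control_profile, fit, np.array([0.0, 0.5]))


def test_detect_bragg_peaks_positions(control_profile, control_truth):
    q_pk, _, _ = detect_bragg_peaks(control_profile)
    D = control_truth.step_params.D
    orders = np.round(q_pk * D / (2 * np.pi))
    np.testing.assert_allclose(q_pk, 2 * np.pi * orders / D, atol=0.01)
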