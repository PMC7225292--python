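"""The three weighted least-squares fitters and the bias correction."""

import numpy as np
import pytest

from nicedwi import (
    ADCModel,
    AcquisitionDesign,
    DWISeries,
    apply_bias_correction,
    bias_factor_c,
    dwls_fit,
    iwls_fit,
    siwls_fit,
)

from conftest import make_clean_series, make_noisy_series


class TestNoiseFreeRecovery:
    def test_dwls_exact(self, clean_series):
        fit = dwls_fit(clean_series)
        np.testing.assert_allclose(fit.adc_map, 1.1e-3, rtol=1e-8)
        np.testing.assert_allclose(np.exp(fit.ln_s0_map), 100.0, rtol=1e-8)

    def test_iwls_exact_fast_zero_sigma(self, clean_series):
        fit = iwls_fit(clean_series)
        np.testing.assert_allclose(fit.adc_map, 1.1e-3, rtol=1e-10)
        assert np.all(fit.iterations_map <= 2)
        assert fit.converged_map.all()
        np.testing.assert_allclose(fit.sigma_nu_sq_map, 0.0, atol=1e-20)
        np.testing.assert_allclose(fit.sigma_adc_map, 0.0, atol=1e-12)


class TestDWLS:
    def test_requires_three_repeats(self):
        series = make_clean_series(M=2)
        with pytest.raises(ValueError, match="3 excitations"):
            dwls_fit(series)

    def test_zero_variance_duplicates_give_two_point_line(self):
        """Two b-values with exact-duplicate triplets: the fit is the
        ordinary two-point log-linear interpolation."""
        b = np.array([0.0] * 3 + [1000.0] * 3)
        sig = np.array([4.0] * 3 + [2.0] * 3).reshape(1, 1, 1, -1)
        fit = dwls_fit(DWISeries(sig, b))
        expected_adc = (np.log(4.0) - np.log(2.0)) / 1000.0
        assert fit.adc_map[0, 0, 0] == pytest.approx(expected_adc, rel=1e-10)
        assert fit.ln_s0_map[0, 0, 0] == pytest.approx(np.log(4.0), rel=1e-10)

    def test_weights_are_inverse_empirical_variance(self):
        """Against an independent generic WLS solve (statsmodels) using
        1/Var weights computed by hand."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        b = np.repeat([50.0, 600.0, 900.0], 4)
        sig = np.exp(np.log(50.0) - b * 1.2e-3 + rng.normal(0, 0.03, b.size))
        fit = dwls_fit(DWISeries(sig.reshape(1, 1, 1, -1), b))
        y = np.log(sig)
        w = np.empty_like(b)
        for bv in np.unique(b):
            w[b == bv] = 1.0 / y[b == bv].var(ddof=1)
        X = np.column_stack([b, np.ones_like(b)])
        sm_fit = sm.WLS(y, X, weights=w).fit()
        assert fit.adc_map[0, 0, 0] == pytest.approx(-sm_fit.params[0], rel=1e-9)
        # parameter covariance is (B'WB)^-1 with absolute weights (no
        # residual-variance factor)
        cov = np.linalg.inv(X.T @ (w[:, None] * X))
        assert fit.sigma_adc_map[0, 0, 0] == pytest.approx(np.sqrt(cov[0, 0]), rel=1e-9)


class TestIWLS:
    def test_matches_independent_wls_at_converged_weights(self):
        """Given the converged weights, the solution equals a textbook
        weighted normal-equations solve on a small random instance."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        b = np.array([0.0, 250.0, 500.0, 750.0, 1000.0])
        sig = np.exp(-b * 1e-3 + rng.normal(0, 0.02, b.size))
        fit = iwls_fit(DWISeries(sig.reshape(1, 1, 1, -1), b))
        X = np.column_stack([b, np.ones_like(b)])
        alpha = np.array([-fit.adc_map[0, 0, 0], fit.ln_s0_map[0, 0, 0]])
        w = np.exp(2.0 * X @ alpha)
        sm_fit = sm.WLS(np.log(sig), X, weights=w).fit()
        np.testing.assert_allclose(alpha, sm_fit.params, rtol=1e-4)
        assert fit.k == 3.0

    def test_equal_weights_reduce_to_ols(self):
        """When the empirical variances agree across b-values the DWLS
        weights are all equal and the fit is the ordinary LS line."""
        b = np.repeat([50.0, 600.0, 900.0], 3)
        d = 0.05
        y = (np.log(10.0) - 1e-3 * b) + np.tile([-d, 0.0, d], 3)
        fit = dwls_fit(DWISeries(np.exp(y).reshape(1, 1, 1, -1), b))
        slope, intercept = np.polyfit(b, y, 1)
        assert fit.adc_map[0, 0, 0] == pytest.approx(-slope, rel=1e-9)
        assert fit.ln_s0_map[0, 0, 0] == pytest.approx(intercept, rel=1e-9)

    def test_weight_consistency_at_convergence(self, noisy_series):
        """Converged weights equal exp(2*B*alpha): the inverse log-domain
        noise variance up to the global sigma_nu^2."""
        fit = iwls_fit(noisy_series)
        B = noisy_series.design().design_matrix
        alpha = np.stack([-fit.adc_map, fit.ln_s0_map], axis=-1)
        w = np.exp(2.0 * alpha @ B.T)
        # re-solving with these weights must reproduce alpha (fixed point)
        Y = np.log(noisy_series.signal)
        flat_w = w.reshape(-1, B.shape[0])
        flat_y = Y.reshape(-1, B.shape[0])
        for v in range(0, flat_w.shape[0], 17):
            wm = flat_w[v]
            refit = np.linalg.solve(
                B.T @ (wm[:, None] * B), B.T @ (wm * flat_y[v])
            )
            np.testing.assert_allclose(
                refit, alpha.reshape(-1, 2)[v], rtol=1e-3, atol=3e-5
            )

    def test_convergence_fast_at_decent_snr(self):
        """The overwhelming majority of voxels converge within 5 iterations."""
        series = make_noisy_series(shape=(16, 16, 2), snr=20.0, seed=4)
        fit = iwls_fit(series)
        frac = np.mean(fit.iterations_map[fit.fitted_mask] <= 5)
        assert fit.converged_map.all()
        assert frac >= 0.97

    def test_nonpositive_entries_excluded_not_clipped(self):
        b = np.repeat([50.0, 600.0, 900.0], 3)
        sig = np.exp(-b * 1e-3)
        sig = np.tile(sig, (1, 1, 1, 1)).reshape(1, 1, 1, -1).copy()
        sig[0, 0, 0, 4] = 0.0  # one dead measurement
        fit = iwls_fit(DWISeries(sig, b))
        assert np.isfinite(fit.adc_map[0, 0, 0])
        assert fit.adc_map[0, 0, 0] == pytest.approx(1e-3, rel=1e-6)

    def test_unfittable_voxel_is_nan(self):
        b = np.repeat([50.0, 600.0, 900.0], 3)
        sig = np.zeros((1, 1, 1, 9))
        fit = iwls_fit(DWISeries(sig, b))
        assert np.isnan(fit.adc_map[0, 0, 0])
        assert fit.n_unfittable == 1

    def test_mask_restricts_fit(self, noisy_series):
        mask = np.zeros(noisy_series.shape, bool)
        mask[0, 0, 0] = True
        noisy_series.mask = mask
        fit = iwls_fit(noisy_series)
        assert np.isfinite(fit.adc_map[0, 0, 0])
        assert np.isnan(fit.adc_map[~mask]).all()


class TestSIWLS:
    def test_omega_one_identical_to_iwls(self, noisy_series):
        a = iwls_fit(noisy_series)
        s = siwls_fit(noisy_series, omega=1)
        np.testing.assert_array_equal(a.sigma_adc_map, s.sigma_adc_map)
        np.testing.assert_array_equal(a.adc_map, s.adc_map)

    def test_effective_dof_scales_with_kernel_area(self, noisy_series):
        s = siwls_fit(noisy_series, omega=3)
        assert s.k == 25.0 * 9
        s3d = siwls_fit(noisy_series, omega=3, dims="3D")
        assert s3d.k == 25.0 * 27

    def test_constant_variance_field_unchanged(self, clean_series):
        """Smoothing a spatially constant residual-variance field is a
        no-op, so sigma_ADC matches IWLS."""
        s = siwls_fit(clean_series, omega=3)
        a = iwls_fit(clean_series)
        np.testing.assert_allclose(s.sigma_adc_map, a.sigma_adc_map, atol=1e-15)

    @pytest.mark.parametrize("omega", [0, -3, 2, 4])
    def test_invalid_omega_rejected(self, noisy_series, omega):
        with pytest.raises(ValueError, match="omega"):
            siwls_fit(noisy_series, omega=omega)

    def test_unknown_kernel_rejected(self, noisy_series):
        with pytest.raises(ValueError, match="kernel"):
            siwls_fit(noisy_series, omega=3, kernel="gauss")


class TestBiasCorrection:
    def test_divides_by_c_of_k(self, noisy_series):
        fit = iwls_fit(noisy_series)
        corr = apply_bias_correction(fit)
        np.testing.assert_allclose(
            corr.sigma_adc_map, fit.sigma_adc_map / bias_factor_c(25), rtol=1e-12
        )
        assert corr.bias_corrected and not fit.bias_corrected

    def test_k1_factor_is_sqrt_2_over_pi(self):
        b = np.array([50.0, 600.0, 900.0])
        rng = np.random.default_rng(2)
        sig = np.exp(-b * 1e-3) + rng.normal(0, 0.01, (2, 2, 1, 3))
        fit = iwls_fit(DWISeries(np.abs(sig), b))
        assert fit.k == 1.0
        corr = apply_bias_correction(fit)
        ratio = corr.sigma_adc_map / fit.sigma_adc_map
        np.testing.assert_allclose(ratio, 1.0 / np.sqrt(2.0 / np.pi), rtol=1e-12)

    def test_double_application_rejected(self, noisy_series):
        corr = apply_bias_correction(iwls_fit(noisy_series))
        with pytest.raises(RuntimeError, match="already"):
            apply_bias_correction(corr)


class TestResultsObject:
    def test_summary_contains_key_facts(self, noisy_series):
        fit = ADCModel(noisy_series).fit("iwls")
        text = fit.summary()
        assert "IWLS" in text and "25" in text and "median ADC" in text

    def test_model_validates_design_match(self, noisy_series):
        wrong = AcquisitionDesign.from_bvalues([0.0, 900.0])
        with pytest.raises(ValueError, match="rows"):
            ADCModel(noisy_series, wrong)
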