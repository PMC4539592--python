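"""Spectral line-shape models, initial guesses, per-pixel least-squares
fits, and the R^2 score."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import spectralgp as sg

GAUSS = sg.GaussianParams(amplitude=100.0, center_nm=470.0, sigma_nm=30.0)
GAMMA = sg.GammaVariateParams(
    amplitude=80.0, onset_nm=400.0, shape=4.0, scale_nm=20.0
)


class TestModels:
    def test_gaussian_closed_form_and_symmetry(self):
        assert sg.gaussian_model(470.0, GAUSS) == pytest.approx(100.0)
        assert sg.gaussian_model(500.0, GAUSS) == pytest.approx(
            100.0 * math.exp(-0.5)
        )
        for d in (1.0, 17.3, 60.0):
            assert sg.gaussian_model(470.0 + d, GAUSS) == pytest.approx(
                sg.gaussian_model(470.0 - d, GAUSS)
            )

    def test_gamma_variate_onset_peak_and_skew(self):
        assert sg.gamma_variate_model(400.0, GAMMA) == 0.0
        assert sg.gamma_variate_model(390.0, GAMMA) == 0.0
        peak = GAMMA.peak_nm
        assert peak == pytest.approx(480.0)
        assert sg.gamma_variate_model(peak, GAMMA) == pytest.approx(80.0)
        # small shape => red tail heavier than blue tail
        skewed = sg.GammaVariateParams(
            amplitude=1.0, onset_nm=400.0, shape=3.0, scale_nm=20.0
        )
        w = 2 * skewed.scale_nm
        assert sg.gamma_variate_model(
            skewed.peak_nm + w, skewed
        ) > sg.gamma_variate_model(skewed.peak_nm - w, skewed)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sg.GaussianParams(amplitude=-1.0, center_nm=470.0, sigma_nm=30.0)
        with pytest.raises(ValueError):
            sg.GammaVariateParams(
                amplitude=1.0, onset_nm=400.0, shape=0.0, scale_nm=20.0
            )


class TestInitialGuess:
    def test_gaussian_guess_near_true_peak(self, axis32):
        y = sg.gaussian_model(axis32.centers_nm, GAUSS)
        guess = sg.initial_guess(y, axis32, "gaussian")
        assert abs(guess.center_nm - 470.0) <= axis32.width_nm
        assert guess.amplitude == pytest.approx(y.max())

    def test_single_nonzero_channel_degenerates_gracefully(self, axis32):
        y = np.zeros(32)
        y[10] = 5.0
        guess = sg.initial_guess(y, axis32, "gaussian")
        assert guess.center_nm == pytest.approx(axis32.centers_nm[10])
        assert guess.sigma_nm == pytest.approx(axis32.width_nm / 2)

    def test_all_zero_spectrum_is_an_error(self, axis32):
        with pytest.raises(ValueError, match="empty spectrum"):
            sg.initial_guess(np.zeros(32), axis32, "gaussian")


class TestRSquared:
    def test_reference_values(self):
        y = np.array([0.0, 1.0, 2.0])
        assert sg.r_squared(y, y) == pytest.approx(1.0)
        assert sg.r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
        assert sg.r_squared(y, np.array([0.0, 1.0, 3.0])) == pytest.approx(0.5)

    def test_constant_observation_is_undefined(self):
        assert math.isnan(sg.r_squared(np.ones(5), np.ones(5)))

    def test_shape_errors(self):
        with pytest.raises(ValueError):
            sg.r_squared(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            sg.r_squared(np.ones(1), np.ones(1))


class TestFitSpectrum:
    @pytest.mark.parametrize(
        "model_kind, params, model",
        [
            ("gaussian", GAUSS, sg.gaussian_model),
            ("gamma_variate", GAMMA, sg.gamma_variate_model),
        ],
    )
    def test_noiseless_parameters_recovered_exactly(
        self, axis32, model_kind, params, model
    ):
        """Identifiability: noiseless model data returns the generating
        parameters to 1e-6 relative and a perfect R^2."""
        y = model(axis32.centers_nm, params)
        fit = sg.fit_spectrum(y, axis32, model_kind)
        assert fit.converged
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        if model_kind == "gaussian":
            assert fit.params.amplitude == pytest.approx(100.0, rel=1e-6)
            assert fit.params.center_nm == pytest.approx(470.0, rel=1e-6)
            assert fit.params.sigma_nm == pytest.approx(30.0, rel=1e-6)
        else:
            assert fit.params.amplitude == pytest.approx(80.0, rel=1e-6)
            assert fit.params.peak_nm == pytest.approx(480.0, abs=1e-4)
            assert fit.params.shape == pytest.approx(4.0, rel=1e-6)
            assert fit.params.scale_nm == pytest.approx(20.0, rel=1e-6)

    def test_gamma_variate_reaches_the_gaussian_limit(self, axis32):
        """The gamma model nests the symmetric case: fitting Gaussian
        data leaves essentially no residual."""
        y = sg.gaussian_model(
            axis32.centers_nm, sg.GaussianParams(100.0, 470.0, 25.0)
        )
        fit = sg.fit_spectrum(y, axis32, "gamma_variate")
        assert fit.converged
        assert fit.r_squared > 0.999

    def test_skewed_spectra_prefer_the_gamma_variate(self, axis32):
        """Right-skewed emission is fitted better by the gamma variate
        than by the symmetric Gaussian."""
        skewed = sg.GammaVariateParams(
            amplitude=100.0, onset_nm=406.0, shape=3.0, scale_nm=15.0
        )
        y = sg.gamma_variate_model(axis32.centers_nm, skewed)
        r2_gamma = sg.fit_spectrum(y, axis32, "gamma_variate").r_squared
        r2_gauss = sg.fit_spectrum(y, axis32, "gaussian").r_squared
        assert r2_gamma > r2_gauss

    def test_scale_equivariance(self, axis32):
        """Scaling the spectrum scales only the amplitude; shape
        parameters and R^2 are unchanged."""
        rng = np.random.default_rng(8)
        y = rng.poisson(
            sg.gaussian_model(axis32.centers_nm, GAUSS) + 3.0
        ).astype(float)
        c = 7.0
        f1 = sg.fit_spectrum(y, axis32, "gaussian")
        f2 = sg.fit_spectrum(c * y, axis32, "gaussian")
        assert f2.params.amplitude == pytest.approx(c * f1.params.amplitude, rel=1e-6)
        assert f2.params.center_nm == pytest.approx(f1.params.center_nm, abs=1e-6)
        assert f2.params.sigma_nm == pytest.approx(f1.params.sigma_nm, rel=1e-6)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-9)

        g1 = sg.fit_spectrum(y, axis32, "gamma_variate")
        g2 = sg.fit_spectrum(c * y, axis32, "gamma_variate")
        assert g2.params.amplitude == pytest.approx(
            c * g1.params.amplitude, rel=1e-6
        )
        assert g2.params.shape == pytest.approx(g1.params.shape, rel=1e-6)
        assert g2.r_squared == pytest.approx(g1.r_squared, abs=1e-9)

    def test_gaussian_shift_equivariance(self):
        """Shifting the wavelength axis shifts the fitted center."""
        delta = 37.0
        axis_a = sg.WavelengthAxis(415.0, 8.9, 32)
        axis_b = sg.WavelengthAxis(415.0 + delta, 8.9, 32)
        y = sg.gaussian_model(axis_a.centers_nm, GAUSS)
        fa = sg.fit_spectrum(y, axis_a, "gaussian")
        fb = sg.fit_spectrum(y, axis_b, "gaussian")
        assert fb.params.center_nm == pytest.approx(
            fa.params.center_nm + delta, abs=1e-6
        )

    def test_all_zero_spectrum_flags_non_convergence(self, axis32):
        fit = sg.fit_spectrum(np.zeros(32), axis32, "gaussian")
        assert not fit.converged
        assert math.isnan(fit.r_squared)
        with pytest.raises(ValueError):
            sg.evaluate_fit(fit, 440.0)

    def test_wrong_length_rejected(self, axis32):
        with pytest.raises(ValueError):
            sg.fit_spectrum(np.ones(31), axis32, "gaussian")

    @pytest.mark.parametrize(
        "model_kind, params, true_peak",
        [
            ("gaussian", sg.GaussianParams(400.0, 470.0, 25.0), 470.0),
            (
                "gamma_variate",
                sg.GammaVariateParams(400.0, 400.0, 4.0, 20.0),
                480.0,
            ),
        ],
    )
    def test_fitted_peak_unbiased_under_shot_noise(
        self, axis32, model_kind, params, true_peak
    ):
        """Monte-Carlo: at peak SNR 20 (Poisson) the mean fitted peak
        wavelength over 1000 replicates stays within 0.5 nm of truth."""
        model = (
            sg.gaussian_model if model_kind == "gaussian" else sg.gamma_variate_model
        )
        clean = model(axis32.centers_nm, params)
        rng = np.random.default_rng(123)
        peaks = []
        for _ in range(1000):
            y = rng.poisson(clean).astype(float)
            fit = sg.fit_spectrum(y, axis32, model_kind)
            if not fit.converged:
                continue
            peaks.append(
                fit.params.center_nm
                if model_kind == "gaussian"
                else fit.params.peak_nm
            )
        assert len(peaks) >= 990
        assert abs(np.mean(peaks) - true_peak) <= 0.5


class TestEvaluateFit:
    def test_matches_dense_grid_oracle(self, axis32):
        """Continuous evaluation agrees with a brute-force 0.01 nm grid
        lookup of the same fitted curve to 1e-6 relative."""
        y = sg.gamma_variate_model(axis32.centers_nm, GAMMA)
        fit = sg.fit_spectrum(y, axis32, "gamma_variate")
        grid = np.arange(415.0, 700.0, 0.01)
        dense = sg.gamma_variate_model(grid, fit.params)
        for lam in (440.0, 480.0, 490.0, 555.5):
            oracle = dense[np.argmin(np.abs(grid - lam))]
            assert sg.evaluate_fit(fit, lam) == pytest.approx(
                oracle, rel=1e-6
            )

    def test_peak_readout_equals_amplitude(self, axis32):
        y = sg.gaussian_model(axis32.centers_nm, sg.GaussianParams(100.0, 440.0, 25.0))
        fit = sg.fit_spectrum(y, axis32, "gaussian")
        assert sg.evaluate_fit(fit, 440.0) == pytest.approx(100.0, rel=1e-6)

    def test_symmetric_peak_between_readouts_gives_zero_gp(self, axis32):
        """A Gaussian centered midway between 440 and 490 nm reads equal
        blue and red intensities, hence GP = 0."""
        p = sg.GaussianParams(100.0, 465.0, 25.0)
        y = sg.gaussian_model(axis32.centers_nm, p)
        fit = sg.fit_spectrum(y, axis32, "gaussian")
        i_b = sg.evaluate_fit(fit, 440.0)
        i_r = sg.evaluate_fit(fit, 490.0)
        assert i_b == pytest.approx(100.0 * math.exp(-0.5), rel=1e-6)
        assert sg.gp_value(i_b, i_r) == pytest.approx(0.0, abs=1e-9)
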