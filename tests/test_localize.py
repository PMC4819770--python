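"""Localization estimators and the precision formula."""

import math

import numpy as np
import pytest

from nanofish.core import (Emitter, FrameGeometry, NoiseModel, OpticsModel,
                           ROI, UnfittableSpotError)
from nanofish.detect import extract_roi
from nanofish.localize import (fit_gaussian_lsq, fit_gaussian_mle,
                               gaussian_model_image, initial_estimate,
                               localization_precision, localize_centroid,
                               model_photons, photons_from_counts,
                               theoretical_width)
from nanofish.synthetic import render_spot

from conftest import spot_roi


class TestTheoreticalWidth:
    @pytest.mark.parametrize("lam,na,expected", [
        (650.0, 1.45, 94.14), (594.0, 1.45, 86.03)])
    def test_reference_values(self, lam, na, expected):
        assert theoretical_width(lam, na) == pytest.approx(expected, abs=0.01)

    def test_linear_in_wavelength(self):
        assert theoretical_width(1300, 1.4) == pytest.approx(
            2 * theoretical_width(650, 1.4))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            theoretical_width(-650, 1.45)
        with pytest.raises(ValueError):
            theoretical_width(650, 0)


class TestInitialEstimate:
    def test_brightest_pixel_and_perimeter_background(self):
        data = np.full((9, 9), 100.0)
        data[4, 4] = 500.0
        roi = ROI(data, anchor=(0, 0), pixel_size_nm=200.0)
        init = initial_estimate(roi, 94.1)
        assert init.z0 == 100.0
        assert init.A == 400.0
        assert init.x0_nm == (4 + 0.5) * 200.0
        assert init.y0_nm == (4 + 0.5) * 200.0
        assert init.sx_nm == init.sy_nm == 94.1
        assert init.theta == 0.0

    def test_uniform_roi_unfittable(self):
        roi = ROI(np.full((9, 9), 100.0), anchor=(0, 0), pixel_size_nm=200.0)
        with pytest.raises(UnfittableSpotError):
            initial_estimate(roi, 94.1)

    def test_tie_broken_row_major(self):
        data = np.zeros((9, 9))
        data[2, 3] = data[6, 1] = 50.0
        roi = ROI(data, anchor=(0, 0), pixel_size_nm=100.0)
        init = initial_estimate(roi, 50.0)
        assert (init.y0_nm, init.x0_nm) == ((2 + 0.5) * 100.0, (3 + 0.5) * 100.0)


class TestLsqFit:
    def test_peak_of_model_is_z0_plus_A(self):
        roi = ROI(np.zeros((9, 9)), anchor=(0, 0), pixel_size_nm=10.0)
        # narrow spot relative to the pixel: integral ~ point sample
        img = gaussian_model_image(roi, z0=7.0, A=100.0, x0_nm=45.0,
                                   y0_nm=45.0, sx_nm=60.0, sy_nm=60.0)
        assert img[4, 4] == pytest.approx(107.0, rel=5e-3)

    def test_noiseless_recovery(self, frame, noiseless):
        optics = OpticsModel(650.0, 1.45)
        roi = spot_roi(3205.0, 3190.0, 5000.0, frame, optics, noiseless,
                       shot_noise=False)
        fit = fit_gaussian_lsq(roi, s_theory_nm=94.14)
        assert fit.converged
        assert fit.x0_nm == pytest.approx(3205.0, abs=0.1)
        assert fit.y0_nm == pytest.approx(3190.0, abs=0.1)

    def test_iteration_bookkeeping(self, frame, optics_a):
        roi = spot_roi(3205.0, 3190.0, 5000.0, frame, optics_a,
                       NoiseModel(10.0), seed=3)
        fit = fit_gaussian_lsq(roi)
        assert fit.converged
        assert 1 <= fit.n_iterations <= 100
        assert fit.residual_ss >= 0

    def test_rmse_tracks_precision_formula(self, frame, optics_a):
        """Monte-Carlo: per-axis scatter of the fitted center matches the
        precision formula within [0.8, 1.3] at N=5000, b=10."""
        rng = np.random.default_rng(11)
        s = theoretical_width(optics_a.wavelength_nm, optics_a.numerical_aperture)
        errs = []
        for _ in range(300):
            x = 3200.0 + rng.uniform(-100, 100)
            y = 3200.0 + rng.uniform(-100, 100)
            roi = spot_roi(x, y, 5000.0, frame, optics_a, NoiseModel(10.0),
                           rng=rng)
            fit = fit_gaussian_lsq(roi)
            if fit.converged:
                errs.append(fit.x0_nm - x)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        sigma = localization_precision(s, 5000.0, 200.0, math.sqrt(10.0))
        assert 0.8 * sigma <= rmse <= 1.3 * sigma


class TestEstimatorProperties:
    def test_noiseless_estimators_agree(self, frame, noiseless):
        """All three estimators land on the same point at zero noise."""
        optics = OpticsModel(650.0, 1.45)
        roi = spot_roi(3210.0, 3185.0, 5000.0, frame, optics, noiseless,
                       shot_noise=False)
        lsq = fit_gaussian_lsq(roi, s_theory_nm=94.14)
        mle = fit_gaussian_mle(roi, s_theory_nm=94.14)
        cx, cy = localize_centroid(roi)
        assert abs(lsq.x0_nm - mle.x0_nm) < 0.1
        assert abs(lsq.y0_nm - mle.y0_nm) < 0.1
        # the centroid of a symmetric spot in a symmetric ROI is unbiased
        # only up to truncation of the tails; compare against truth
        assert cx == pytest.approx(3210.0, abs=2.0)
        assert cy == pytest.approx(3185.0, abs=2.0)

    def test_centroid_tracks_subpixel_shift(self, frame, noiseless):
        optics = OpticsModel(650.0, 1.45)
        a = frame.pixel_size_nm
        x0 = (16 + 0.5) * a
        roi0 = spot_roi(x0, x0, 5000.0, frame, optics, noiseless,
                        shot_noise=False)
        roi1 = spot_roi(x0 + 0.3 * a, x0, 5000.0, frame, optics, noiseless,
                        shot_noise=False)
        shift = localize_centroid(roi1)[0] - localize_centroid(roi0)[0]
        assert shift == pytest.approx(0.3 * a, abs=0.05 * a)

    def test_mle_deviance_improves_on_init(self, frame, optics_a):
        roi = spot_roi(3205.0, 3190.0, 1000.0, frame, optics_a,
                       NoiseModel(10.0), seed=5)
        init = initial_estimate(roi, 94.14)
        fit = fit_gaussian_mle(roi, init=init)
        # deviance at the optimum cannot exceed deviance at the start
        init_fit = fit_gaussian_mle(roi, init=init, max_iterations=0)
        assert fit.residual_ss <= init_fit.residual_ss + 1e-9

    def test_centroid_noise_sensitivity(self, frame, optics_a):
        """At low SNR the centroid scatters more than the LSQ fit."""
        rng = np.random.default_rng(21)
        errs_c, errs_l = [], []
        for _ in range(150):
            x = 3200.0 + rng.uniform(-100, 100)
            roi = spot_roi(x, 3200.0, 800.0, frame, optics_a,
                           NoiseModel(20.0), rng=rng)
            try:
                cx, _ = localize_centroid(roi)
                fit = fit_gaussian_lsq(roi)
            except UnfittableSpotError:
                continue
            if fit.converged:
                errs_c.append(cx - x)
                errs_l.append(fit.x0_nm - x)
        rmse_c = np.sqrt(np.mean(np.square(errs_c)))
        rmse_l = np.sqrt(np.mean(np.square(errs_l)))
        assert rmse_c > rmse_l


class TestPhotonsAndPrecision:
    def test_photon_recovery_noiseless(self, frame, noiseless):
        optics = OpticsModel(650.0, 1.45)
        roi = spot_roi(3205.0, 3190.0, 1000.0, frame, optics, noiseless,
                       shot_noise=False, half_width=6)
        fit = fit_gaussian_lsq(roi, s_theory_nm=94.14)
        assert photons_from_counts(roi, fit) == pytest.approx(1000.0, abs=5.0)
        assert model_photons(fit, 200.0) == pytest.approx(1000.0, rel=0.01)

    def test_gain_invariance(self, frame):
        optics = OpticsModel(650.0, 1.45)
        em = Emitter(3205.0, 3190.0, 1000.0)
        for gain in (1.0, 2.0):
            img = render_spot(em, frame, optics, NoiseModel(0.0, 0.0, gain),
                              shot_noise=False)
            roi = extract_roi(img, (15, 16), 6)
            fit = fit_gaussian_lsq(roi, s_theory_nm=94.14)
            assert photons_from_counts(roi, fit) == pytest.approx(1000.0, abs=5.0)

    def test_background_only_roi_has_no_photons(self):
        roi = ROI(np.full((9, 9), 50.0), anchor=(0, 0), pixel_size_nm=200.0)
        fit_like = type("F", (), {"z0": 50.0})
        assert photons_from_counts(roi, fit_like) == 0.0

    @pytest.mark.parametrize("s,N,a,b,expected", [
        (100.0, 1000.0, 200.0, 0.0, 3.651),
        (100.0, 1000.0, 200.0, 10.0, 4.430),
    ])
    def test_precision_formula_reference_values(self, s, N, a, b, expected):
        assert localization_precision(s, N, a, b) == pytest.approx(expected,
                                                                   abs=0.001)

    def test_precision_decreases_with_photons(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            s = rng.uniform(50, 200)
            n = rng.uniform(10, 1e5)
            a = rng.uniform(50, 400)
            b = rng.uniform(0, 50)
            assert localization_precision(s, 2 * n, a, b) < \
                localization_precision(s, n, a, b)

    def test_precision_undefined_without_photons(self):
        with pytest.raises(ValueError):
            localization_precision(100.0, 0.0, 200.0, 0.0)
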