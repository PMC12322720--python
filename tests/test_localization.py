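"""Wavelet detection and Poisson-MLE spot fitting."""

import numpy as np
import pytest
from scipy.special import erf

from nwloc.image_synthesis import CameraModel
from nwloc.localization import (
    DETECTION_COLUMNS,
    LocalizationParams,
    atrous_decompose,
    atrous_filter,
    estimate_noise_sigma0,
    find_candidates,
    fisher_information,
    fit_psf_mle,
    localize_frame,
)


def _spot(shape, x, y, photons, sigma, background=0.0):
    """Noiseless pixel-integrated Gaussian spot in photon units."""
    rows = np.arange(shape[0], dtype=float)
    cols = np.arange(shape[1], dtype=float)
    s = sigma * np.sqrt(2.0)
    ex = 0.5 * (erf((cols + 0.5 - x) / s) - erf((cols - 0.5 - x) / s))
    ey = 0.5 * (erf((rows + 0.5 - y) / s) - erf((rows - 0.5 - y) / s))
    return background + photons * np.outer(ey, ex)


class TestAtrous:
    def test_exact_reconstruction(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100.0, 10.0, size=(64, 64))
        details, smooth = atrous_decompose(img, 4)
        assert len(details) == 4
        assert np.allclose(sum(details) + smooth, img, atol=1e-9)

    def test_invalid_levels_and_size(self):
        with pytest.raises(ValueError):
            atrous_decompose(np.zeros((32, 32)), 0)
        with pytest.raises(ValueError):
            atrous_decompose(np.zeros((8, 8)), 3)  # kernel support 17 > 8
        with pytest.raises(ValueError):
            atrous_filter(np.zeros((64, 64)), n_levels=3, detection_plane=4)

    def test_noise_sigma_estimate_oracle(self):
        rng = np.random.default_rng(1)
        for sd in (2.0, 10.0):
            img = rng.normal(500.0, sd, size=(128, 128))
            assert estimate_noise_sigma0(img) == pytest.approx(sd, rel=0.1)

    def test_noise_estimate_robust_to_spots(self):
        # a few bright spots must not inflate the noise estimate
        rng = np.random.default_rng(2)
        img = rng.normal(0.0, 5.0, size=(128, 128))
        for r, c in [(30, 30), (60, 90), (100, 40)]:
            img += _spot(img.shape, c, r, 5000.0, 1.1)
        assert estimate_noise_sigma0(img) == pytest.approx(5.0, rel=0.15)

    def test_filter_suppresses_pure_noise(self):
        rng = np.random.default_rng(3)
        img = rng.normal(100.0, 4.0, size=(128, 128))
        det = atrous_filter(img, k_sigma=3.0)
        # a 3-sigma hard threshold leaves only a tiny fraction of pixels
        assert np.mean(det > 0) < 0.01

    def test_filter_keeps_spot(self):
        rng = np.random.default_rng(4)
        img = rng.normal(100.0, 4.0, size=(128, 128))
        img += _spot(img.shape, 64.0, 64.0, 2000.0, 1.1)
        det = atrous_filter(img)
        assert det[64, 64] > 0

    def test_noise_sigma0_override_raises_threshold(self):
        rng = np.random.default_rng(5)
        img = rng.normal(100.0, 4.0, size=(128, 128))
        img += _spot(img.shape, 64.0, 64.0, 400.0, 1.1)
        assert atrous_filter(img)[64, 64] > 0
        # anchoring to a much larger reference noise floor removes the spot
        assert atrous_filter(img, noise_sigma0=100.0)[64, 64] == 0.0


class TestFindCandidates:
    def test_two_separated_spots(self):
        img = _spot((96, 96), 25.0, 30.0, 1000.0, 1.1)
        img += _spot((96, 96), 70.0, 60.0, 800.0, 1.1)
        rc = find_candidates(img)
        assert len(rc) == 2
        assert {tuple(r) for r in rc} == {(30, 25), (60, 70)}

    def test_close_maxima_merged_keep_brighter(self):
        img = np.zeros((64, 64))
        img[30, 30] = 10.0
        img[30, 32] = 8.0  # within min_separation_px=3
        rc = find_candidates(img, gradient_threshold=0.0)
        assert [tuple(r) for r in rc] == [(30, 30)]

    def test_empty_input(self):
        assert find_candidates(np.zeros((32, 32))).shape == (0, 2)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            find_candidates(np.zeros((32, 32)), min_separation_px=-1)


class TestFitPsfMle:
    CAM = CameraModel(shape=(64, 64))

    def _frame(self, x, y, photons, background, seed=None):
        mu = _spot((64, 64), x, y, photons, 1.08, background)
        if seed is None:
            counts = mu
        else:
            counts = np.random.default_rng(seed).poisson(mu)
        return counts * self.CAM.gain + self.CAM.dark_offset

    def test_recovers_known_parameters_noiseless(self):
        frame = self._frame(31.3, 28.6, 2000.0, 5.0)
        fit = fit_psf_mle(frame, (29, 31), self.CAM)
        assert fit is not None and fit.converged
        assert fit.x_px == pytest.approx(31.3, abs=0.02)
        assert fit.y_px == pytest.approx(28.6, abs=0.02)
        assert fit.photons == pytest.approx(2000.0, rel=0.05)
        assert fit.background == pytest.approx(5.0, rel=0.2)
        assert fit.sigma_px == pytest.approx(1.08, rel=0.05)

    def test_window_outside_frame_returns_none(self):
        frame = self._frame(2.0, 2.0, 1000.0, 5.0)
        assert fit_psf_mle(frame, (1, 1), self.CAM) is None

    def test_insignificant_spot_rejected(self):
        # a fit on pure background fails the photon-significance gate
        frame = self._frame(31.0, 31.0, 0.0, 20.0, seed=0)
        fit = fit_psf_mle(frame, (31, 31), self.CAM)
        assert fit is None

    def test_precision_matches_crlb_oracle(self):
        # localization RMSE over repeated noisy fits must track the CRLB:
        # within 25 % at N=1000, and ~halve when N quadruples
        x_true, y_true, bkg = 31.4, 30.7, 10.0
        rmse = {}
        crlb = {}
        for n_ph in (1000.0, 4000.0):
            errs = []
            for s in range(300):
                frame = self._frame(x_true, y_true, n_ph, bkg, seed=1000 + s)
                fit = fit_psf_mle(frame, (31, 31), self.CAM)
                assert fit is not None
                errs.append(fit.x_px - x_true)
            rmse[n_ph] = np.sqrt(np.mean(np.square(errs)))
            info = fisher_information(3.4, 2.7, n_ph, 1.08, bkg, 7)
            crlb[n_ph] = np.sqrt(np.linalg.inv(info)[0, 0])
        assert rmse[1000.0] == pytest.approx(crlb[1000.0], rel=0.25)
        assert rmse[4000.0] == pytest.approx(0.5 * rmse[1000.0], rel=0.35)

    def test_reported_uncertainty_is_crlb(self):
        frame = self._frame(31.0, 31.0, 1000.0, 10.0)
        fit = fit_psf_mle(frame, (31, 31), self.CAM)
        info = fisher_information(3.0, 3.0, fit.photons, fit.sigma_px,
                                  fit.background, 7)
        expected = np.sqrt(np.linalg.inv(info)[0, 0])
        assert fit.sigma_x_px == pytest.approx(expected, rel=1e-6)


class TestLocalizeFrame:
    CAM = CameraModel(shape=(128, 128))

    def _frame(self, emitters, background=12.0, seed=0):
        mu = np.full(self.CAM.shape, background)
        for x, y, n in emitters:
            mu += _spot(self.CAM.shape, x, y, n, 1.08)
        counts = np.random.default_rng(seed).poisson(mu)
        return counts * self.CAM.gain + self.CAM.dark_offset

    def test_detects_all_separated_emitters(self):
        truth = [(30.2, 40.7, 2000.0), (80.6, 25.3, 1500.0), (60.0, 100.0, 2500.0)]
        df = localize_frame(self._frame(truth), self.CAM)
        assert len(df) == 3
        assert list(df.columns) == DETECTION_COLUMNS
        for x, y, n in truth:
            d = np.hypot(df["x_px"] - x, df["y_px"] - y)
            i = int(np.argmin(d))
            assert d.iloc[i] < 0.3
            assert df["photons"].iloc[i] == pytest.approx(n, rel=0.15)

    def test_positions_reported_in_both_units(self):
        df = localize_frame(self._frame([(50.0, 50.0, 3000.0)]), self.CAM)
        assert len(df) == 1
        assert df["x_um"].iloc[0] == pytest.approx(
            (df["x_px"].iloc[0] + 0.5) * self.CAM.pixel_size_um
        )

    def test_empty_frame_gives_empty_table(self):
        rng = np.random.default_rng(7)
        frame = rng.poisson(12.0, size=self.CAM.shape) + self.CAM.dark_offset
        df = localize_frame(frame.astype(float), self.CAM)
        assert list(df.columns) == DETECTION_COLUMNS
        assert len(df) == 0

    def test_two_overlapping_emitters_deduplicated(self):
        # two emitters closer than min_separation_px yield a single detection
        df = localize_frame(
            self._frame([(50.0, 50.0, 2000.0), (51.0, 50.5, 1800.0)]), self.CAM
        )
        assert len(df) == 1

    def test_deterministic_given_frame(self):
        frame = self._frame([(30.0, 30.0, 2000.0)], seed=3)
        a = localize_frame(frame, self.CAM)
        b = localize_frame(frame, self.CAM)
        assert a.equals(b)

    def test_params_object_respected(self):
        # an absurdly high k_sigma suppresses every detection
        frame = self._frame([(50.0, 50.0, 2000.0)])
        p = LocalizationParams(k_sigma=1e6)
        assert len(localize_frame(frame, self.CAM, p)) == 0
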