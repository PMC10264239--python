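"""SOFI engine: corrections, cross-cumulants, flattening, deconvolution."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from exmkit import synthgen
from exmkit.morphometry import fit_gaussian_fwhm
from exmkit.sofi import (BlinkingMovie, correct_drift, correct_intensity,
                         distance_factor_flatten, gaussian_psf,
                         lucy_richardson, sofi_pipeline, xc_sofi2)
from exmkit.synthgen import EmitterField, gen_blinking_movie

from conftest import single_emitter_movie


def static_poisson_movie(frames=50, level=50.0, shape=(64, 64), seed=9):
    em = EmitterField.random(40, shape, amplitude=1000.0, seed=seed)
    base = synthgen.render_emitters(em.positions, em.amplitudes, shape,
                                    1.5) + level
    rng = np.random.default_rng(seed)
    data = rng.poisson(np.broadcast_to(base, (frames,) + shape)).astype(float)
    return BlinkingMovie(data, 100.0)


class TestDriftCorrection:
    def test_static_movie_untouched(self):
        movie = static_poisson_movie()
        out, shifts = correct_drift(movie)
        assert np.abs(shifts).max() < 0.1
        np.testing.assert_allclose(out.data, movie.data, atol=1e-6)

    def test_linear_drift_recovered(self):
        errs = []
        for seed in range(3):
            em = EmitterField.from_dwell_times(
                EmitterField.random(40, (64, 64), seed=seed).positions,
                np.full(40, 1000.0), 20.0, 5.0, seed=seed)
            movie, _ = gen_blinking_movie(em, 300.0, 100.0, shape=(64, 64),
                                          frames=100, drift=(0.05, 0.02),
                                          seed=seed)
            _, shifts = correct_drift(movie)
            t = np.arange(100)
            rate_x = np.polyfit(t, -shifts[:, 1], 1)[0]
            rate_y = np.polyfit(t, -shifts[:, 0], 1)[0]
            errs.append(np.hypot((rate_x - 0.05) * 99, (rate_y - 0.02) * 99))
        assert np.median(errs) < 0.2

    def test_single_frame_passthrough(self):
        movie = BlinkingMovie(np.random.default_rng(0).poisson(
            50, (1, 16, 16)).astype(float), 100.0)
        out, shifts = correct_drift(movie)
        np.testing.assert_array_equal(shifts, 0.0)
        np.testing.assert_array_equal(out.data, movie.data)

    def test_featureless_movie_warns(self):
        movie = BlinkingMovie(np.full((5, 16, 16), 3.0), 100.0)
        with pytest.warns(UserWarning, match="featureless"):
            out, shifts = correct_drift(movie)
        np.testing.assert_array_equal(out.data, movie.data)


class TestIntensityCorrection:
    def test_constant_movie_unchanged(self):
        movie = BlinkingMovie(np.full((20, 8, 8), 40.0), 100.0)
        for method in ("global_mean", "exp_fit"):
            out = correct_intensity(movie, method=method)
            np.testing.assert_allclose(out.data, movie.data, rtol=1e-9)

    def test_exponential_bleach_removed(self):
        base = np.full((100, 16, 16), 500.0)
        decay = np.exp(-0.005 * np.arange(100))[:, None, None]
        movie = BlinkingMovie(base * decay, 100.0)
        out = correct_intensity(movie, method="exp_fit")
        means = out.data.mean(axis=(1, 2))
        assert (means.max() - means.min()) / means.mean() < 0.01
        assert means[0] == pytest.approx(500.0, rel=1e-6)

    def test_global_mean_equalizes_to_first_frame(self):
        rng = np.random.default_rng(4)
        movie = BlinkingMovie(rng.uniform(10, 50, (10, 8, 8)), 100.0)
        out = correct_intensity(movie, method="global_mean")
        means = out.data.mean(axis=(1, 2))
        np.testing.assert_allclose(means, means[0], rtol=1e-12)

    def test_all_zero_movie_rejected(self):
        movie = BlinkingMovie(np.zeros((5, 8, 8)), 100.0)
        with pytest.raises(ValueError, match="empty frame"):
            correct_intensity(movie, method="global_mean")
        with pytest.raises(ValueError, match="empty frame"):
            correct_intensity(movie, method="exp_fit")


class TestCrossCumulant:
    def test_static_movie_gives_zero_cumulant(self):
        movie = BlinkingMovie(np.full((20, 16, 16), 37.0), 100.0)
        cum = xc_sofi2(movie)
        assert np.abs(cum.data).max() < 1e-9 * 37.0
        assert cum.data.shape == (31, 31)
        assert cum.pixel_nm_effective == 50.0

    def test_virtual_grid_shape_and_lag_validation(self):
        movie = BlinkingMovie(np.random.default_rng(0).poisson(
            20, (10, 8, 12)).astype(float), 100.0)
        assert xc_sofi2(movie).data.shape == (15, 23)
        with pytest.raises(ValueError):
            xc_sofi2(movie, lag=0)
        with pytest.raises(ValueError):
            xc_sofi2(movie, lag=9)

    def test_cumulant_psf_narrower_by_sqrt2(self):
        movie, truth = single_emitter_movie(seed=3, frames=10000,
                                            poisson=False)
        cum = xc_sofi2(movie, lag=1)
        flat = distance_factor_flatten(cum,
                                       psf_sigma_px=truth["psf_sigma_px"])
        fwhm_mean = fit_gaussian_fwhm(movie.mean_image(), window=8)
        fwhm_cum = fit_gaussian_fwhm(flat.data, window=12) / 2.0  # virtual px
        assert fwhm_cum / fwhm_mean == pytest.approx(1 / np.sqrt(2),
                                                     rel=0.05)

    def test_poisson_background_suppressed_at_lag1(self):
        rng = np.random.default_rng(5)
        level = 1000.0
        data = rng.poisson(level, (100, 32, 32)).astype(float)
        cum = xc_sofi2(BlinkingMovie(data, 100.0), lag=1)
        phys = cum.data[::2, ::2]
        # expectation -var/T (mean-subtraction bias), SD ~ var/sqrt(T-1)
        pred_sd = level / np.sqrt(99)
        bias = -level / 100.0
        assert abs(phys.mean() - bias) < 3 * pred_sd / np.sqrt(phys.size)
        assert phys.std() == pytest.approx(pred_sd, rel=0.3)

    def test_cumulant_quadratic_in_brightness(self):
        em1 = EmitterField([[16, 16]], [1000.0], 0.5, 5.0, 5.0, seed=2)
        em2 = EmitterField([[16, 16]], [2000.0], 0.5, 5.0, 5.0, seed=2)
        kw = dict(shape=(33, 33), frames=500, poisson=False, seed=2)
        m1, _ = gen_blinking_movie(em1, 300.0, 100.0, **kw)
        m2, _ = gen_blinking_movie(em2, 300.0, 100.0, **kw)
        c1 = xc_sofi2(m1).data.max()
        c2 = xc_sofi2(m2).data.max()
        assert c2 / c1 == pytest.approx(4.0, rel=0.05)


class TestFlattening:
    def test_uniform_field_flattens_to_unit_class_ratio(self):
        em = EmitterField.random(150, (48, 48), amplitude=500.0,
                                 mean_on_frames=5, mean_off_frames=5,
                                 margin=3, seed=8)
        movie, truth = gen_blinking_movie(em, 300.0, 100.0, shape=(48, 48),
                                          frames=4000, poisson=False, seed=8)
        cum = xc_sofi2(movie)
        flat = distance_factor_flatten(cum,
                                       psf_sigma_px=truth["psf_sigma_px"])
        inner = flat.data[10:-10, 10:-10]
        ratio = (np.abs(inner[::2, 1::2]).mean()
                 / np.abs(inner[::2, ::2]).mean())
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_zero_cumulant_stays_zero(self):
        from exmkit.sofi import CumulantImage

        cum = CumulantImage(np.zeros((31, 31)), 50.0)
        out = distance_factor_flatten(cum, psf_sigma_px=1.3)
        assert np.all(out.data == 0.0)
        with pytest.raises(ValueError, match="empty"):
            distance_factor_flatten(cum, calibration="self_calibrated")

    def test_physical_vs_virtual_site_equal_peak(self):
        kw = dict(shape=(33, 33), frames=8000, poisson=False)
        peaks = []
        for x in (16.0, 16.5):
            em = EmitterField([[x, 16.0]], [1000.0], 0.5, 5.0, 5.0, seed=4)
            movie, truth = gen_blinking_movie(em, 300.0, 100.0, seed=4, **kw)
            flat = distance_factor_flatten(
                xc_sofi2(movie), psf_sigma_px=truth["psf_sigma_px"])
            peaks.append(flat.data.max())
        assert peaks[1] / peaks[0] == pytest.approx(1.0, abs=0.1)


class TestLucyRichardson:
    def test_delta_psf_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, (32, 32))
        psf = np.zeros((5, 5))
        psf[2, 2] = 1.0
        for n in (1, 10, 50):
            np.testing.assert_allclose(lucy_richardson(img, psf, n), img,
                                       rtol=1e-9)

    def test_sharpens_and_conserves_flux(self):
        psf = gaussian_psf(2.0)
        img = np.zeros((65, 65))
        img[32, 32] = 1000.0
        from scipy.signal import fftconvolve

        blurred = np.clip(fftconvolve(img, psf, mode="same"), 0, None)
        prev_fwhm = fit_gaussian_fwhm(blurred, window=10)
        for n in (10, 30, 50):
            out = lucy_richardson(blurred, psf, n)
            fwhm = fit_gaussian_fwhm(out, window=10)
            assert fwhm < prev_fwhm
            prev_fwhm = fwhm
            assert out.sum() == pytest.approx(blurred.sum(), rel=0.01)
            assert out.min() >= 0.0

    def test_invalid_inputs_rejected(self):
        img = np.ones((8, 8))
        with pytest.raises(ValueError):
            lucy_richardson(img, np.zeros((3, 3)), 10)
        with pytest.raises(ValueError):
            lucy_richardson(img, gaussian_psf(1.0), 0)


class TestPipeline:
    def test_resolves_subdiffraction_pair_median_dip(self):
        """Two emitters at 0.6x the Rayleigh separation: unresolved in the
        temporal mean, >= 20% median intensity dip after SOFI + RL."""
        fwhm_px = 3.0
        sep = 0.6 * (1.22 / 1.03) * fwhm_px  # Rayleigh ~ 1.18x FWHM
        dips, mean_resolved = [], []
        for seed in range(10):
            pos = [[16 - sep / 2, 16], [16 + sep / 2, 16]]
            em = EmitterField(pos, [3000.0, 3000.0], 0.5, 2.0, 2.0,
                              seed=seed)
            movie, _ = gen_blinking_movie(em, 300.0, 100.0, shape=(33, 33),
                                          frames=100, poisson=False,
                                          seed=seed)
            mrow = movie.mean_image()[16]
            pk, _ = find_peaks(mrow)
            mean_resolved.append(len(pk) >= 2)
            out, _ = sofi_pipeline(movie, 300.0, rl_iterations=500)
            prof = out[29:36, 26:40].sum(axis=0)
            pk, _ = find_peaks(prof)
            if len(pk) < 2:
                dips.append(0.0)
            else:
                top = np.sort(pk[np.argsort(prof[pk])[-2:]])
                mid = prof[top[0]:top[1] + 1].min()
                dips.append(1 - mid / prof[top].min())
        assert not any(mean_resolved)
        assert np.median(dips) >= 0.2

    def test_static_uniform_movie_near_zero(self):
        movie = BlinkingMovie(np.full((50, 16, 16), 20.0), 100.0)
        with pytest.warns(UserWarning, match="featureless"):
            out, _ = sofi_pipeline(movie, 300.0)
        assert np.abs(out).max() < 1e-6

    def test_accepts_minimum_acquisition_length(self):
        movie, _ = single_emitter_movie(seed=0, frames=50)
        out, log = sofi_pipeline(movie, 300.0)
        assert out.shape == (65, 65)
        assert log["pixel_nm_effective"] == 50.0

    def test_deterministic(self):
        movie, _ = single_emitter_movie(seed=1, frames=60)
        o1, _ = sofi_pipeline(movie, 300.0)
        o2, _ = sofi_pipeline(movie, 300.0)
        np.testing.assert_array_equal(o1, o2)
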