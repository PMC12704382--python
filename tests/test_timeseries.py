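"""Background thresholds, apical series extraction, detrending and smoothing."""

import numpy as np
import pytest

import tipflux as tf
from tipflux.movie import Movie
from tipflux.timeseries import moving_average, savgol_trend

from conftest import SMALL_ACQ, truth_track


def small_config(**kwargs) -> tf.SyntheticMovieConfig:
    return tf.SyntheticMovieConfig(acquisition=SMALL_ACQ, **kwargs)


def sg_response(period_samples: float, window: int = 10, degree: int = 2) -> complex:
    """Transfer-function oracle for the local-quadratic trend filter.

    The trend weights solve the least-squares Vandermonde system evaluated at
    offset 0 (asymmetric window for even lengths); the response at a period is
    the weighted sum of complex exponentials.
    """
    offsets = np.arange(window, dtype=float) - window // 2
    V = np.vander(offsets, degree + 1, increasing=True)
    w = np.linalg.pinv(V)[0]
    return complex(np.sum(w * np.exp(-2j * np.pi * offsets / period_samples)))


class TestThresholds:
    def test_constant_background_threshold_is_constant(self):
        movie = Movie(np.full((5, 60, 60), 42.0))
        thr = tf.extracellular_threshold(movie, roi=(0, 0, 50, 50))
        assert thr.value == pytest.approx(42.0)

    def test_gaussian_background_leaves_upper_tail(self):
        """mean + 2 SD keeps ~97.7% of N(100, 5) background below threshold."""
        rng = np.random.default_rng(0)
        movie = Movie(rng.normal(100.0, 5.0, (20, 80, 80)))
        thr = tf.extracellular_threshold(movie, roi=(0, 0, 50, 50))
        assert thr.value == pytest.approx(110.0, abs=0.5)
        above = (movie.pixels >= thr.value).mean()
        assert above == pytest.approx(0.0228, abs=0.005)

    def test_thresholds_are_per_acquisition(self):
        rng = np.random.default_rng(1)
        a = Movie(rng.normal(100, 2, (5, 60, 60)))
        b = Movie(rng.normal(100, 9, (5, 60, 60)))
        ta = tf.extracellular_threshold(a, roi=(0, 0, 50, 50))
        tb = tf.extracellular_threshold(b, roi=(0, 0, 50, 50))
        assert tb.value > ta.value + 5

    def test_cytosolic_above_extracellular(self):
        """Technique 2 sits above technique 1 whenever cytosol outshines the
        extracellular background."""
        sm = tf.generate_movie(small_config(seed=3))
        t1 = tf.extracellular_threshold(sm.movie)
        t2 = tf.cytosolic_threshold(sm.movie, track=truth_track(sm))
        assert t2.value > t1.value

    def test_cytosolic_constant_roi(self):
        movie = Movie(np.full((25, 60, 60), 7.0))
        thr = tf.cytosolic_threshold(movie, roi=(10, 10, 16, 16))
        assert thr.value == pytest.approx(7.0)
        assert thr.frames_used == (0, 20)

    def test_cytosolic_quantile_on_control(self):
        """The threshold clears ~97.7% of cytosolic values in frames 0-19."""
        sm = tf.generate_movie(small_config(regime="control", seed=5))
        thr = tf.cytosolic_threshold(sm.movie, track=truth_track(sm))
        x0, y0, w, h = thr.roi
        vals = sm.pixels[:20, y0 : y0 + h, x0 : x0 + w].ravel()
        assert (vals < thr.value).mean() == pytest.approx(0.977, abs=0.01)

    def test_short_movie_warns(self):
        movie = Movie(np.random.default_rng(0).random((8, 40, 40)))
        with pytest.warns(UserWarning, match="frames"):
            tf.cytosolic_threshold(movie, roi=(5, 5, 16, 16))


class TestApplyThreshold:
    def test_zero_threshold_masks_nothing(self):
        movie = Movie(np.random.default_rng(0).random((3, 10, 10)) + 1.0)
        out = tf.apply_threshold(movie, 0.0)
        assert np.isfinite(out.pixels).all()

    def test_above_max_masks_everything(self):
        movie = Movie(np.random.default_rng(0).random((3, 10, 10)))
        out = tf.apply_threshold(movie, 2.0)
        assert np.isnan(out.pixels).all()

    def test_idempotent(self):
        movie = Movie(np.random.default_rng(1).normal(0, 1, (4, 20, 20)))
        once = tf.apply_threshold(movie, 0.3)
        twice = tf.apply_threshold(once, 0.3)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_masked_fraction_matches_normal_tail(self):
        rng = np.random.default_rng(2)
        movie = Movie(rng.normal(100, 5, (30, 64, 64)))
        thr = tf.extracellular_threshold(movie, roi=(0, 0, 50, 50))
        masked = np.isnan(tf.apply_threshold(movie, thr).pixels).mean()
        assert masked == pytest.approx(0.977, abs=0.01)


class TestApicalSeries:
    def test_uniform_intensity_gives_constant_series(self):
        pixels = np.full((6, 50, 50), 5.0)
        sm = tf.generate_movie(small_config(seed=1, elongation_rate_um_per_min=0.0))
        tracked = tf.crop_to_track(Movie(np.full_like(sm.pixels, 5.0)), truth_track(sm))
        series = tf.apical_mean_series(tracked)
        np.testing.assert_allclose(series.values, 5.0)
        assert series.missing_counts.sum() == 0

    def test_all_masked_frame_flagged(self):
        sm = tf.generate_movie(small_config(seed=1, elongation_rate_um_per_min=0.0))
        pixels = np.full_like(sm.pixels, np.nan)
        tracked = tf.crop_to_track(Movie(pixels), truth_track(sm))
        series = tf.apical_mean_series(tracked)
        assert np.isnan(series.values).all()

    def test_control_series_variability_matches_noise_oracle(self):
        """Control series fluctuations reflect averaged pixel noise plus the
        stochastic masking of near-threshold pixels, not structured dynamics:
        the detrended SD stays within the noise scale."""
        sm = tf.generate_movie(small_config(regime="control", seed=7))
        thr = tf.extracellular_threshold(sm.movie)
        cropped = tf.crop_to_track(tf.apply_threshold(sm.movie, thr), truth_track(sm))
        detrended = tf.detrend(tf.apical_mean_series(cropped))
        assert np.nanstd(detrended.values) < 1.0  # intensity units, noise sd 5 / ~sqrt(N)


class TestDetrend:
    def test_quadratic_reproduced_exactly(self):
        t = np.arange(60.0)
        y = 3.0 + 0.5 * t - 0.02 * t**2
        d = tf.detrend(y)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-8)

    def test_decomposition_is_exact(self):
        y = np.random.default_rng(0).normal(0, 1, 135)
        d = tf.detrend(y)
        np.testing.assert_allclose(d.values + d.trend, y, atol=1e-12)

    def test_ramp_removed_sinusoid_attenuated_per_filter_response(self):
        """A linear ramp vanishes; the sinusoid passes with amplitude
        1 - |H(f)| as given by the filter frequency-response oracle."""
        t = np.arange(400.0)
        period = 10.0
        y = 5.0 + 0.3 * t + np.sin(2 * np.pi * t / period)
        d = tf.detrend(y)
        interior = d.values[30:-30]
        expected = abs(1.0 - sg_response(period))
        measured = np.ptp(interior) / 2.0
        assert measured == pytest.approx(expected, rel=0.10)
        # the ramp leaves no residual slope
        assert abs(np.polyfit(t[30:-30], interior, 1)[0]) < 1e-4

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            tf.detrend(np.arange(8.0))

    def test_nan_gaps_fit_on_finite_points(self):
        y = np.sin(np.arange(80.0) / 5.0) + 2.0
        y_gap = y.copy()
        y_gap[40] = np.nan
        d = tf.detrend(y_gap)
        assert np.isnan(d.values[40])  # the gap itself stays missing
        assert np.isfinite(d.trend[40])  # but the local trend bridges it
        d_full = tf.detrend(y)
        np.testing.assert_allclose(d.trend[:30], d_full.trend[:30], atol=0.05)

    def test_even_and_odd_windows_agree_on_smooth_trends(self):
        """Window 10 (half-sample shifted) and window 11 give near-identical
        trends for polynomial signals; they differ materially only when the
        signal has structure at the window scale."""
        t = np.arange(135.0)
        y = 100.0 + 0.8 * t - 0.003 * t**2
        d10 = savgol_trend(y, 10, 2)
        d11 = savgol_trend(y, 11, 2)
        assert np.sqrt(np.mean((d10 - d11) ** 2)) / np.std(y) < 1e-6


class TestSmoothForFFT:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(tf.smooth_for_fft(np.full(50, 3.0)), 3.0)

    def test_white_noise_variance_reduced(self):
        x = np.random.default_rng(3).normal(0, 1, 200)
        assert tf.smooth_for_fft(x).var() < x.var()

    def test_reference_period_attenuation_matches_transfer_oracle(self):
        """A 44.55-s sinusoid sampled at 4.455 s passes SG + moving-average
        smoothing with the gain the combined transfer function predicts
        (~0.66), and its period is unchanged."""
        t = np.arange(270.0) * 4.455
        y = np.sin(2 * np.pi * t / 44.55)
        sm = tf.smooth_for_fft(y)
        amp = np.ptp(sm[30:-30]) / 2.0
        k = np.arange(-1, 2)
        ma_gain = np.sum(np.exp(-2j * np.pi * k / 10.0)) / 3.0
        expected = abs(sg_response(10.0) * ma_gain)
        assert amp == pytest.approx(expected, rel=0.05)
        spec = tf.amplitude_spectrum(sm, 4.455)
        assert tf.dominant_peak(spec).period_s == pytest.approx(44.55, abs=0.5)

    def test_moving_average_edges_shrink(self):
        out = moving_average(np.array([1.0, 2.0, 3.0, 4.0]), 3)
        np.testing.assert_allclose(out, [1.5, 2.0, 3.0, 3.5])
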