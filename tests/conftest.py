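"""Shared fixtures: synthetic movies, analyzed cohorts, truth-based tracks."""

from __future__ import annotations

import numpy as np
import pytest

import tipflux as tf
from tipflux.movie import AcquisitionSpec
from tipflux.tracking import RoiTrack

#: Reduced field for tests that render many movies; geometry (tube width,
#: cap, blob, noise) is unchanged, only the empty margins shrink.
SMALL_ACQ = AcquisitionSpec(height_px=120, width_px=176)


def truth_track(sm: tf.SyntheticMovie, roi_size_px: int = 50, anchor_um: float = 1.0) -> RoiTrack:
    """Build an ROI track directly from generator ground truth."""
    movie = sm.movie
    tips = sm.truth.tip_positions
    u = np.asarray(sm.truth.growth_axis, float)
    half = roi_size_px / 2.0
    centers = tips - (half - anchor_um / movie.pixel_size_um) * u
    H, W = movie.pixels.shape[1:]
    centers = centers.copy()
    centers[:, 0] = np.clip(centers[:, 0], half, W - half)
    centers[:, 1] = np.clip(centers[:, 1], half, H - half)
    return RoiTrack(roi_size_px, centers, tips.copy(), tuple(u), threshold=np.nan)


@pytest.fixture(scope="session")
def spitzen_movie() -> tf.SyntheticMovie:
    """One oscillatory movie at the reference period, full field."""
    return tf.generate_movie(tf.SyntheticMovieConfig(seed=11, oscillation_period_s=44.55))


@pytest.fixture(scope="session")
def analyzed_cohort():
    """Default 18-movie cohort analyzed through tracking, series and TDC.

    Returns per-movie truths, TDC features, detrended technique-2 FFT inputs
    and the clustering of the feature vectors (the standard workflow).
    """
    movies = tf.generate_cohort(seed=1)
    out = {"truths": [], "features": [], "fft_series": [], "rates": [], "roundness": []}
    for sm in movies:
        movie = sm.movie
        thr1 = tf.extracellular_threshold(movie)
        track = tf.track_apex(movie, threshold=thr1.value)
        thr2 = tf.cytosolic_threshold(movie, track=track)
        crop1 = tf.crop_to_track(tf.apply_threshold(movie, thr1), track)
        crop2 = tf.crop_to_track(tf.apply_threshold(movie, thr2), track)
        d1 = tf.detrend(tf.apical_mean_series(crop1))
        d2 = tf.detrend(tf.apical_mean_series(crop2))
        proj = tf.time_project(crop1)
        region = tf.top_fraction_mask(proj)
        rate = tf.estimate_growth_rate(track.tip_positions, movie.frame_interval_s, movie.pixel_size_um)
        out["truths"].append(sm.truth)
        out["features"].append(tf.tdc_features(d1.values))
        out["fft_series"].append(tf.smooth_for_fft(d2))
        out["rates"].append(rate.rate_um_per_min)
        out["roundness"].append(region.roundness)
    out["clustering"] = tf.cluster_features(out["features"], seed=1)
    out["regimes"] = [t.regime for t in out["truths"]]
    return out
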