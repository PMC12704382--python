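"""Apical mean-intensity time series with background suppression.

Two thresholding techniques convert a tracked movie into a per-frame apical
mean-intensity series:

* technique 1 (*extracellular*): threshold = mean + 2 SD of a 50x50 px
  extracellular ROI over all frames, so ~95% of extracellular pixels fall
  below it; restricts measurements to the inside of the hypha.
* technique 2 (*cytosolic*): threshold = mean + 2 SD of a 16x16 px subapical
  ROI (5 ± 2 µm behind the tip) over the first 20 frames; restricts
  measurements to regions of strong fluorescence.

Below-threshold pixels become NaN; per-frame means are taken over unmasked
pixels within 4 µm of the tip along the growth axis.  Series are detrended by
subtracting a Savitzky-Golay trend (window 10, polynomial degree 2) without
normalization, preserving the relative amplitude of short-term fluctuations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from .movie import Movie
from .tracking import RoiTrack, TrackedMovie, _largest_foreground

logger = logging.getLogger("tipflux")

EXTRACELLULAR_ROI_PX = 50
CYTOSOL_ROI_PX = 16
CYTOSOL_N_FRAMES = 20
CYTOSOL_OFFSET_UM = 5.0
DEFAULT_APICAL_EXTENT_UM = 4.0
SG_WINDOW = 10
SG_DEGREE = 2
MA_WINDOW = 3


@dataclass(frozen=True)
class IntensityThreshold:
    """A mean + 2 SD background-suppression threshold."""

    technique: str  # "extracellular" or "cytosolic"
    value: float
    roi: tuple  # (x0, y0, width, height) in pixels
    frames_used: tuple  # (first, last+1)


@dataclass
class ApicalSeries:
    """Per-frame mean apical intensity with missing-value provenance."""

    values: np.ndarray
    interval_s: float
    apical_extent_um: float
    missing_counts: np.ndarray  # per-frame count of masked apical pixels

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.interval_s


@dataclass
class DetrendedSeries:
    """Trend-subtracted series; ``values + trend`` reconstructs the input."""

    values: np.ndarray
    trend: np.ndarray
    filter_params: dict = field(default_factory=dict)


def _roi_values(pixels: np.ndarray, roi: tuple, frames: slice) -> np.ndarray:
    x0, y0, w, h = roi
    return pixels[frames, y0 : y0 + h, x0 : x0 + w]


def _auto_extracellular_roi(movie: Movie, size: int) -> tuple:
    """Place the ROI at the frame corner farthest from the hypha."""
    from skimage.filters import threshold_otsu

    frame0 = movie.pixels[0]
    finite = frame0[np.isfinite(frame0)]
    rough = threshold_otsu(finite)
    mask = _largest_foreground(frame0, rough)
    H, W = frame0.shape
    if mask is None:
        return (W - size, 0, size, size)
    ys, xs = np.nonzero(mask)
    centroid = np.array([xs.mean(), ys.mean()])
    corners = [(0, 0), (W - size, 0), (0, H - size), (W - size, H - size)]
    best = max(
        corners,
        key=lambda c: np.linalg.norm(np.array([c[0] + size / 2, c[1] + size / 2]) - centroid),
    )
    return (best[0], best[1], size, size)


def extracellular_threshold(movie: Movie, roi: tuple | None = None, roi_size_px: int = EXTRACELLULAR_ROI_PX) -> IntensityThreshold:
    """Threshold technique 1: mean + 2 SD of an extracellular ROI, all frames."""
    if roi is None:
        roi = _auto_extracellular_roi(movie, roi_size_px)
    vals = _roi_values(movie.pixels, roi, slice(None))
    value = float(np.nanmean(vals) + 2 * np.nanstd(vals))
    return IntensityThreshold("extracellular", value, tuple(roi), (0, movie.n_frames))


def cytosolic_threshold(
    movie: Movie,
    track: RoiTrack | None = None,
    roi: tuple | None = None,
    n_frames: int = CYTOSOL_N_FRAMES,
    roi_size_px: int = CYTOSOL_ROI_PX,
) -> IntensityThreshold:
    """Threshold technique 2: mean + 2 SD of a subapical ROI, first 20 frames.

    If no ROI is given, a 16x16 window is auto-placed 5 µm behind the frame-0
    tip along the growth axis (requires ``track``).
    """
    if roi is None:
        if track is None:
            raise ValueError("either an explicit ROI or a track is required")
        u = np.asarray(track.growth_axis)
        center = track.tip_positions[0] - (CYTOSOL_OFFSET_UM / movie.pixel_size_um) * u
        H, W = movie.pixels.shape[1:]
        x0 = int(np.clip(round(center[0] - roi_size_px / 2), 0, W - roi_size_px))
        y0 = int(np.clip(round(center[1] - roi_size_px / 2), 0, H - roi_size_px))
        roi = (x0, y0, roi_size_px, roi_size_px)
    if movie.n_frames < n_frames:
        warnings.warn(f"movie has {movie.n_frames} < {n_frames} frames; using all for the cytosolic threshold")
        n_frames = movie.n_frames
    vals = _roi_values(movie.pixels, roi, slice(0, n_frames))
    value = float(np.nanmean(vals) + 2 * np.nanstd(vals))
    return IntensityThreshold("cytosolic", value, tuple(roi), (0, n_frames))


def apply_threshold(movie: Movie, threshold: IntensityThreshold | float) -> Movie:
    """Replace below-threshold pixels with NaN (at-or-above are retained)."""
    value = threshold.value if isinstance(threshold, IntensityThreshold) else float(threshold)
    pixels = np.where(movie.pixels >= value, movie.pixels, np.nan)
    note = f"threshold:{getattr(threshold, 'technique', 'manual')}={value:.4g}"
    return movie.with_pixels(pixels, note)


def apical_mean_series(tracked: TrackedMovie, apical_extent_um: float = DEFAULT_APICAL_EXTENT_UM) -> ApicalSeries:
    """Mean intensity over unmasked pixels within ``apical_extent_um`` of the tip.

    The apical region is the half-plane cut perpendicular to the growth axis
    at ``apical_extent_um`` behind the tip, intersected with the ROI crop.
    Because tracking anchors the tip at a fixed position in the crop, the cut
    is placed relative to the per-movie median tip-in-crop position: the
    measured region is then a fixed pixel set in crop coordinates, so
    sub-pixel jitter of the per-frame tip estimate cannot leak into the
    series.  Frames where every apical pixel is masked yield NaN and are
    flagged.
    """
    T, r, _ = tracked.pixels.shape
    u = np.asarray(tracked.track.growth_axis)
    extent_px = apical_extent_um / tracked.pixel_size_um
    yy, xx = np.mgrid[0:r, 0:r].astype(float)
    values = np.empty(T)
    missing = np.zeros(T, dtype=int)
    tip_ref = np.median(tracked.tips_in_crop, axis=0)
    proj = (xx - tip_ref[0]) * u[0] + (yy - tip_ref[1]) * u[1]
    region = proj >= -extent_px
    for t in range(T):
        vals = tracked.pixels[t][region]
        finite = np.isfinite(vals)
        missing[t] = int((~finite).sum())
        if finite.any():
            values[t] = vals[finite].mean()
        else:
            values[t] = np.nan
            logger.warning("frame %d: no unmasked apical pixels", t)
    return ApicalSeries(values, tracked.frame_interval_s, apical_extent_um, missing)


def savgol_trend(values: np.ndarray, window: int = SG_WINDOW, degree: int = SG_DEGREE) -> np.ndarray:
    """Local least-squares polynomial trend (Savitzky-Golay).

    Supports even window lengths (the fit window is shifted half a sample) and
    NaN gaps (each window is fit on its finite points).  Boundary windows are
    shifted inside the series and the polynomial evaluated at the target index.
    """
    y = np.asarray(values, float)
    n = y.size
    if n <= window:
        raise ValueError(f"series length {n} must exceed the filter window {window}")
    half = window // 2
    x = np.arange(n, dtype=float)
    if np.isfinite(y).all():
        # each output is the local fit evaluated at the sample itself, so a
        # degree-d filter reproduces degree-d polynomials exactly; for even
        # windows the fit window is asymmetric (half a sample shifted)
        trend = np.empty(n)
        weight_cache: dict = {}
        for i in range(n):
            s = int(np.clip(i - half, 0, n - window))
            offsets = tuple(range(s - i, s - i + window))
            if offsets not in weight_cache:
                V = np.vander(np.asarray(offsets, float), degree + 1, increasing=True)
                weight_cache[offsets] = np.linalg.pinv(V)[0]  # evaluation at offset 0
            trend[i] = weight_cache[offsets] @ y[s : s + window]
        return trend
    trend = np.full(n, np.nan)
    for i in range(n):
        s = int(np.clip(i - half, 0, n - window))
        idx = slice(s, s + window)
        fin = np.isfinite(y[idx])
        if fin.sum() <= degree:
            continue
        coeffs = np.polyfit(x[idx][fin] - i, y[idx][fin], degree)
        trend[i] = np.polyval(coeffs, 0.0)
    return trend


def detrend(series, window: int = SG_WINDOW, degree: int = SG_DEGREE) -> DetrendedSeries:
    """Subtract the Savitzky-Golay trend; no normalization is applied."""
    values = series.values if isinstance(series, ApicalSeries) else np.asarray(series, float)
    trend = savgol_trend(values, window, degree)
    return DetrendedSeries(values - trend, trend, {"window": window, "degree": degree})


def moving_average(values: np.ndarray, window: int = MA_WINDOW) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available points."""
    y = np.asarray(values, float)
    half = window // 2
    out = np.empty_like(y)
    for i in range(y.size):
        lo, hi = max(0, i - half), min(y.size, i + window - half)
        w = y[lo:hi]
        fin = np.isfinite(w)
        out[i] = w[fin].mean() if fin.any() else np.nan
    return out


def smooth_for_fft(
    detrended,
    sg_window: int = SG_WINDOW,
    sg_degree: int = SG_DEGREE,
    ma_window: int = MA_WINDOW,
) -> np.ndarray:
    """Savitzky-Golay smoothing followed by a centered moving average."""
    values = detrended.values if isinstance(detrended, DetrendedSeries) else np.asarray(detrended, float)
    return moving_average(savgol_trend(values, sg_window, sg_degree), ma_window)
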