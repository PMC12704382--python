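"""Spatial footprint of apical fluorescence: projection, mask, shape, morphology.

The time projection (pixel-wise mean over frames) summarizes where
fluorescence resided over the acquisition.  The accumulation region is the
top-p% brightest projection pixels (default p = 4.5); its roundness
4*area / (pi * major_axis^2) — 1 for a disc, lower for elongated shapes —
discriminates a stable spheroid (Spitzenkoerper) from a wandering
submembranous signal whose projection is a crescent.  Hyphal width and apex
curvature are measured on the first frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from skimage import measure

from .tracking import _largest_foreground

logger = logging.getLogger("tipflux")

DEFAULT_TOP_PERCENT = 4.5
MIN_RELIABLE_AREA_UM2 = 0.5


class NoContrastError(ValueError):
    """The projection has no intensity contrast to threshold."""


@dataclass
class TimeProjection:
    """Pixel-wise mean over frames, NaN-aware."""

    pixels: np.ndarray  # (Y, X) mean over finite frames per pixel
    counts: np.ndarray  # (Y, X) number of finite frames per pixel
    pixel_size_um: float


@dataclass
class AccumulationRegion:
    """Top-p% accumulation mask and its shape descriptors."""

    mask: np.ndarray
    fraction_p: float
    threshold: float
    area_um2: float
    mean_intensity: float
    roundness: float
    roundness_reliable: bool


@dataclass
class MorphologyMeasures:
    width_um: float
    max_curvature_per_um: float


def time_project(tracked) -> TimeProjection:
    """Average-intensity time projection; masked (NaN) values are excluded.

    Pixels masked in every frame are undefined (NaN) and flagged in ``counts``.
    """
    pixels = tracked.pixels if hasattr(tracked, "pixels") else np.asarray(tracked)
    pixel_size = getattr(tracked, "pixel_size_um", 1.0)
    counts = np.isfinite(pixels).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(pixels, axis=0)
    n_undefined = int((counts == 0).sum())
    if n_undefined:
        logger.info("time projection: %d pixels masked in every frame", n_undefined)
    return TimeProjection(mean, counts, pixel_size)


def top_fraction_mask(
    projection: TimeProjection,
    p_percent: float = DEFAULT_TOP_PERCENT,
    pixel_size_um: float | None = None,
    histogram_bins: int | None = None,
) -> AccumulationRegion:
    """Mask of the top-p% brightest projection pixels.

    The threshold is the (100-p)th percentile (linear interpolation between
    order statistics) of the finite projection values; all pixels at or above
    it are retained, so ties may push the mask slightly past p%.  Roundness is
    flagged unreliable below 0.5 µm², where single-pixel differences dominate.

    ``histogram_bins`` (e.g. 256) switches to an image-software-style
    histogram threshold for integer-valued images: the threshold is the lower
    edge of the first bin whose upper cumulative count reaches p%.
    """
    if not 0 < p_percent <= 100:
        raise ValueError("p_percent must be in (0, 100]")
    img = projection.pixels if isinstance(projection, TimeProjection) else np.asarray(projection, float)
    if pixel_size_um is None:
        pixel_size_um = getattr(projection, "pixel_size_um", 1.0)
    finite = img[np.isfinite(img)]
    if finite.size == 0 or finite.max() == finite.min():
        raise NoContrastError("projection has no intensity contrast")
    if histogram_bins is None:
        threshold = float(np.quantile(finite, 1.0 - p_percent / 100.0))
    else:
        counts, edges = np.histogram(finite, bins=histogram_bins)
        upper_tail = np.cumsum(counts[::-1])[::-1] / finite.size
        threshold = float(edges[np.argmax(upper_tail <= p_percent / 100.0)])
    with np.errstate(invalid="ignore"):
        mask = img >= threshold
    n = int(mask.sum())
    area = n * pixel_size_um**2
    mean_int = float(img[mask].mean())
    reliable = area > MIN_RELIABLE_AREA_UM2
    roundness = measure_roundness(mask)
    if not reliable:
        logger.warning("accumulation region area %.3f um^2 <= %.1f; roundness unreliable", area, MIN_RELIABLE_AREA_UM2)
    return AccumulationRegion(mask, p_percent, threshold, area, mean_int, roundness, reliable)


def measure_roundness(region) -> float:
    """Roundness 4*area / (pi * major_axis^2) of the best-fit ellipse.

    Computed on the largest connected component when the mask is fragmented.
    """
    mask = region.mask if isinstance(region, AccumulationRegion) else np.asarray(region, bool)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValueError("empty mask")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    props = measure.regionprops((labels == counts.argmax()).astype(int))[0]
    major = props.axis_major_length
    if major == 0:  # one or two pixels: degenerate, treat as round
        return 1.0
    return float(min(4.0 * props.area / (np.pi * major**2), 1.0))


def _binary_mask(frame: np.ndarray, threshold: float) -> np.ndarray:
    mask = _largest_foreground(frame, threshold)
    if mask is None:
        raise ValueError("no foreground above threshold")
    return ndimage.binary_fill_holes(mask)


def measure_width(
    frame: np.ndarray,
    tip_xy: np.ndarray,
    growth_axis: tuple,
    pixel_size_um: float,
    threshold: float,
    offsets_um: tuple = (2.1, 3.3, 4.5),
    max_half_width_um: float = 5.0,
) -> float:
    """Hyphal width as the mean of transects behind the tip.

    At each sub-tip distance in ``offsets_um`` (default 3.3 ± 1.2 µm), the
    foreground mask is sampled along the perpendicular to the growth axis and
    the transect length converted to µm.
    """
    mask = _binary_mask(frame, threshold).astype(float)
    u = np.asarray(growth_axis, float)
    v = np.array([-u[1], u[0]])
    tip = np.asarray(tip_xy, float)
    H, W = frame.shape
    ds = 0.25  # px
    s = np.arange(-max_half_width_um / pixel_size_um, max_half_width_um / pixel_size_um + ds, ds)
    widths = []
    for off in offsets_um:
        center = tip - (off / pixel_size_um) * u
        if not (0 <= center[0] <= W - 1 and 0 <= center[1] <= H - 1):
            raise ValueError(f"width transect at {off} um behind the tip exits the frame")
        pts = center[None] + s[:, None] * v[None]
        inside = (pts[:, 0] >= 0) & (pts[:, 0] <= W - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= H - 1)
        vals = np.zeros(len(pts))
        vals[inside] = ndimage.map_coordinates(mask, [pts[inside, 1], pts[inside, 0]], order=1)
        widths.append((vals > 0.5).sum() * ds * pixel_size_um)
    return float(np.mean(widths))


def estimate_apex_curvature(
    frame: np.ndarray,
    tip_xy: np.ndarray,
    growth_axis: tuple,
    pixel_size_um: float,
    threshold: float,
    arc_length_um: float = 10.0,
    smoothing_um: float = 0.02,
    contour_sigma_px: float = 1.0,
) -> float:
    """Curvature (1/µm) of the cell contour at the most apical point.

    The binary foreground mask is lightly Gaussian-smoothed (suppressing
    pixelation of the outline) and its 0.5-level contour extracted; the arc of
    ``arc_length_um`` centered on the tip is fit with a smoothing spline, and
    the curvature |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2) is evaluated at the
    contour point of maximal projection onto the growth axis.
    """
    mask = _binary_mask(frame, threshold)
    contours = measure.find_contours(ndimage.gaussian_filter(mask.astype(float), contour_sigma_px), 0.5)
    if not contours:
        raise ValueError("no contour found")
    tip = np.asarray(tip_xy, float)
    u = np.asarray(growth_axis, float)
    # contour points come as (row, col); convert to (x, y)
    contour = min(contours, key=lambda c: np.min(np.hypot(c[:, 1] - tip[0], c[:, 0] - tip[1])))
    xy = np.column_stack([contour[:, 1], contour[:, 0]])
    closed = np.allclose(xy[0], xy[-1])
    if closed:
        xy = xy[:-1]
    n = len(xy)
    # center the arc on the most apical contour point; near-ties (flat fronts)
    # resolve toward the supplied tip estimate
    proj = xy @ u
    candidates = np.flatnonzero(proj >= proj.max() - 1.0)
    i_tip = int(candidates[np.argmin(np.linalg.norm(xy[candidates] - tip, axis=1))])
    seg = np.hypot(*np.diff(xy, axis=0).T)
    half_pts = int(round((arc_length_um / 2) / (seg.mean() * pixel_size_um)))
    if closed:
        idx = (i_tip + np.arange(-half_pts, half_pts + 1)) % n
    else:
        lo, hi = i_tip - half_pts, i_tip + half_pts + 1
        if lo < 0 or hi > n:
            raise ValueError("contour arc around the apex is shorter than the requested length")
        idx = np.arange(lo, hi)
    arc = xy[idx] * pixel_size_um  # work in µm
    t = np.r_[0, np.cumsum(np.hypot(*np.diff(arc, axis=0).T))]
    smooth = len(arc) * smoothing_um**2
    (tck, _) = interpolate.splprep([arc[:, 0], arc[:, 1]], u=t, s=smooth, k=3)
    # most apical point of the smoothed arc
    uu = np.linspace(t[0], t[-1], 4 * len(arc))
    px, py = interpolate.splev(uu, tck)
    u_apex = uu[np.argmax(px * u[0] + py * u[1])]
    dx, dy = interpolate.splev(u_apex, tck, der=1)
    ddx, ddy = interpolate.splev(u_apex, tck, der=2)
    denom = (dx**2 + dy**2) ** 1.5
    if denom == 0:
        raise ValueError("degenerate contour parameterization")
    return float(abs(dx * ddy - dy * ddx) / denom)
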