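"""Movie containers, acquisition geometry and TIFF input/output.

A movie is a single-channel time-lapse stack indexed ``[t, y, x]`` with physical
calibration (frame interval in seconds, pixel size in micrometers).  Positions in
image space are expressed as ``(x, y)`` floats under the pixel-center convention:
origin at the top-left pixel center, x rightward, y downward.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("tipflux")

#: Confocal acquisition defaults: 4.455 s per frame, 7.3759 px/µm
#: (0.1356 µm pixels), 295x224 px field, 135 frames per 10 min movie.
DEFAULT_FRAME_INTERVAL_S = 4.455
DEFAULT_PIXEL_SIZE_UM = 0.1356
DEFAULT_FRAME_COUNT = 135
DEFAULT_HEIGHT_PX = 224
DEFAULT_WIDTH_PX = 295


@dataclass(frozen=True)
class AcquisitionSpec:
    """Geometry and timing of a time-lapse acquisition."""

    frame_count: int = DEFAULT_FRAME_COUNT
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    height_px: int = DEFAULT_HEIGHT_PX
    width_px: int = DEFAULT_WIDTH_PX

    def __post_init__(self) -> None:
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.height_px <= 0 or self.width_px <= 0:
            raise ValueError("frame dimensions must be positive")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    @property
    def duration_s(self) -> float:
        """Time spanned by the acquisition, first to last frame."""
        return (self.frame_count - 1) * self.frame_interval_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.frame_count) * self.frame_interval_s

    @classmethod
    def from_pixels_per_micron(cls, pixels_per_um: float, **kwargs) -> "AcquisitionSpec":
        """Build a spec from an optical resolution given in pixels per micron."""
        return cls(pixel_size_um=1.0 / pixels_per_um, **kwargs)

    @staticmethod
    def frames_for_duration(duration_s: float, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> int:
        """Number of frames acquired over ``duration_s``, counting the t0 frame."""
        return int(math.floor(duration_s / frame_interval_s)) + 1


@dataclass
class Movie:
    """A single-channel T x Y x X intensity stack with physical calibration.

    ``pixels`` may contain NaN where a background-suppression threshold has
    masked values; ``provenance`` records the processing steps applied.
    """

    pixels: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None]
        if self.pixels.ndim != 3:
            raise ValueError("movie pixels must be a T x Y x X stack")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def with_pixels(self, pixels: np.ndarray, note: str | None = None) -> "Movie":
        prov = list(self.provenance) + ([note] if note else [])
        return Movie(pixels, self.frame_interval_s, self.pixel_size_um, prov)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_movie(movie: Movie, path, quantize_16bit: bool = False, extra_meta: dict | None = None) -> None:
    """Write a movie as a multi-frame grayscale TIFF plus a JSON metadata sidecar.

    Float data are written as float32 unless ``quantize_16bit`` is set, in which
    case intensities are clipped to [0, 65535] and rounded to uint16.
    """
    path = Path(path)
    pixels = np.asarray(movie.pixels)
    if quantize_16bit:
        pixels = np.clip(np.nan_to_num(pixels, nan=0.0), 0, 65535).round().astype(np.uint16)
    else:
        pixels = pixels.astype(np.float32)
    tifffile.imwrite(path, pixels, photometric="minisblack")
    meta = {
        "frame_interval_s": movie.frame_interval_s,
        "pixel_size_um": movie.pixel_size_um,
        "provenance": [str(p) for p in movie.provenance],
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_movie(path) -> Movie:
    """Read a multi-frame grayscale TIFF written by :func:`write_movie`.

    RGB/multi-channel stacks are rejected.  If no metadata sidecar is found,
    the standard acquisition calibration is assumed with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if tif.pages[0].photometric not in (
            tifffile.PHOTOMETRIC.MINISBLACK,
            tifffile.PHOTOMETRIC.MINISWHITE,
        ):
            raise ValueError(f"{path.name}: expected a single-channel grayscale stack")
        pixels = tif.asarray()
    if pixels.ndim not in (2, 3):
        raise ValueError(f"{path.name}: expected a T x Y x X stack, got shape {pixels.shape}")
    sidecar = _sidecar_path(path)
    interval, pixel_size = DEFAULT_FRAME_INTERVAL_S, DEFAULT_PIXEL_SIZE_UM
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        interval = float(meta.get("frame_interval_s", interval))
        pixel_size = float(meta.get("pixel_size_um", pixel_size))
    else:
        warnings.warn(f"{path.name}: no metadata sidecar; assuming {interval} s frames, {pixel_size} um pixels")
    return Movie(pixels.astype(np.float64), interval, pixel_size)
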