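"""Periodicity detection and sinusoidal modeling of apical fluorescence.

The amplitude spectrum of a detrended, smoothed series is

    A(f) = 2 * sqrt(Re^2 + Im^2) / N

with N the pre-padding series length; the factor 2 folds the FFT's symmetric
positive/negative-frequency split, so a pure sinusoid of amplitude a that
completes an integer number of cycles yields A = a at its frequency.  Series
are zero-padded to 16384 points to interpolate the spectrum; the retained
band covers periods from 9 s (Nyquist at a 4.455 s frame interval, rounded
up) to 150 s (at least four full cycles per 10-min acquisition).

A short-time Fourier transform (Hann window, 32-point segments, 50% overlap,
same padding) checks whether the dominant period persists across the movie,
and a sinusoidal model A_p*sin(2*pi*(t - phi)/p) is fit to the series by grid
search over the phase angle (2-degree steps).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import ShortTimeFFT, get_window

logger = logging.getLogger("tipflux")

DEFAULT_PAD_LENGTH = 16384
DEFAULT_MIN_PERIOD_S = 9.0
DEFAULT_MAX_PERIOD_S = 150.0
STFT_SEGMENT = 32
STFT_OVERLAP = 16
THETA_STEP_DEG = 2.0
PEAK_WINDOW_LEVEL = 0.7


@dataclass
class AmplitudeSpectrum:
    """Amplitude per period, restricted to the retained band, periods descending."""

    periods_s: np.ndarray
    amplitudes: np.ndarray
    n_original: int
    pad_length: int
    interval_s: float


@dataclass(frozen=True)
class SpectralPeak:
    period_s: float
    amplitude: float


@dataclass
class Spectrogram:
    """Per-segment amplitude spectra, each normalized to max 1."""

    segment_times_s: np.ndarray
    periods_s: np.ndarray
    normalized_amplitudes: np.ndarray  # (n_periods, n_segments)


@dataclass
class SinusoidModel:
    """Fixed-period sinusoid fit by phase grid search."""

    period_s: float
    amplitude: float
    theta_deg: float
    phase_shift_s: float
    mse: float
    peak_windows_s: list  # [(t_start, t_end), ...] where model > 0.7 * amplitude

    def predict(self, times_s: np.ndarray) -> np.ndarray:
        return self.amplitude * np.sin(2 * np.pi * (times_s - self.phase_shift_s) / self.period_s)


def default_period_band(frame_count: int, interval_s: float, min_cycles: int = 4) -> tuple:
    """Retained period band: [ceil(2*interval), floor(duration/min_cycles)] in s.

    The lower bound rounds the Nyquist period up to a whole second; the upper
    bound requires at least ``min_cycles`` complete cycles in the acquisition.
    """
    return (
        float(math.ceil(2 * interval_s)),
        float(math.floor(frame_count * interval_s / min_cycles)),
    )


def amplitude_spectrum(
    series: np.ndarray,
    interval_s: float,
    pad_length: int = DEFAULT_PAD_LENGTH,
    min_period_s: float = DEFAULT_MIN_PERIOD_S,
    max_period_s: float = DEFAULT_MAX_PERIOD_S,
) -> AmplitudeSpectrum:
    """Zero-padded FFT amplitude spectrum over the retained period band."""
    x = np.asarray(series, float)
    n = x.size
    if not np.isfinite(x).all():
        logger.warning("amplitude_spectrum: %d non-finite values replaced by 0", int((~np.isfinite(x)).sum()))
        x = np.nan_to_num(x, nan=0.0)
    pad = max(pad_length, n)
    X = np.fft.rfft(x, n=pad)
    freqs = np.fft.rfftfreq(pad, d=interval_s)
    amps = 2.0 * np.abs(X) / n
    periods = 1.0 / freqs[1:]
    amps = amps[1:]
    lo = max(min_period_s, 2 * interval_s)  # hard Nyquist guard
    keep = (periods >= lo) & (periods <= max_period_s)
    if not keep.any():
        raise ValueError("no spectral bins in the retained period band")
    return AmplitudeSpectrum(periods[keep], amps[keep], n, pad, interval_s)


def dominant_peak(spectrum: AmplitudeSpectrum) -> SpectralPeak:
    """Period of maximal amplitude; ties break toward the longer period."""
    i = int(np.argmax(spectrum.amplitudes))  # periods descend, so first max = longest
    return SpectralPeak(float(spectrum.periods_s[i]), float(spectrum.amplitudes[i]))


def stft_spectrogram(
    series: np.ndarray,
    interval_s: float,
    segment: int = STFT_SEGMENT,
    overlap: int = STFT_OVERLAP,
    pad_length: int = DEFAULT_PAD_LENGTH,
    max_period_s: float = DEFAULT_MAX_PERIOD_S,
) -> Spectrogram:
    """Hann-windowed short-time spectra, per-segment max-normalized to [0, 1]."""
    x = np.asarray(series, float)
    if x.size < segment:
        raise ValueError(f"series length {x.size} shorter than one segment ({segment})")
    x = np.nan_to_num(x, nan=0.0)
    win = get_window("hann", segment)
    sft = ShortTimeFFT(win, hop=segment - overlap, fs=1.0 / interval_s, mfft=pad_length)
    S = np.abs(sft.stft(x))
    times = sft.t(x.size)
    freqs = sft.f
    periods = np.empty_like(freqs)
    periods[0] = np.inf
    periods[1:] = 1.0 / freqs[1:]
    keep = (periods < max_period_s) & (periods >= 2 * interval_s)
    S = S[keep]
    col_max = S.max(axis=0)
    col_max[col_max == 0] = 1.0
    return Spectrogram(times, periods[keep], S / col_max)


def fit_sinusoid(
    series: np.ndarray,
    interval_s: float,
    period_s: float,
    amplitude: float,
    theta_step_deg: float = THETA_STEP_DEG,
    peak_level: float = PEAK_WINDOW_LEVEL,
) -> SinusoidModel:
    """Fit M_t = A_p * sin(2*pi*(t - phi)/p) by scanning theta in [0, 360).

    phi = theta * p / 360; theta moves on a ``theta_step_deg`` grid (360
    itself is excluded as identical to 0) and the grid point minimizing the
    mean squared error against the series is returned, together with the
    predicted-peak time windows where the model exceeds ``peak_level * A_p``.
    """
    y = np.asarray(series, float)
    t = np.arange(y.size) * interval_s
    fin = np.isfinite(y)
    thetas = np.arange(0.0, 360.0, theta_step_deg)
    phis = thetas * period_s / 360.0
    models = amplitude * np.sin(2 * np.pi * (t[None, :] - phis[:, None]) / period_s)
    mses = np.mean((models[:, fin] - y[fin]) ** 2, axis=1)
    i = int(np.argmin(mses))
    model = models[i]
    above = model > peak_level * amplitude
    edges = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    windows = [(float(t[s]), float(t[min(e, y.size) - 1])) for s, e in zip(edges[::2], edges[1::2])]
    return SinusoidModel(period_s, amplitude, float(thetas[i]), float(phis[i]), float(mses[i]), windows)
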