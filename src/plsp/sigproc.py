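"""Deterministic signal-processing primitives.

Zero-phase FIR band-pass filtering, analytic-signal phase/amplitude
extraction, and instantaneous-frequency estimation with moving-median
smoothing. These are the shared front end of both the real-time loop
(per-window) and the offline scorer (full record).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import filtfilt, firwin, hilbert, lfilter

from .circstats import wrap_angle

__all__ = [
    "BandSpec",
    "AnalyticSeries",
    "ShortSegmentError",
    "fir_bandpass_zero_phase",
    "analytic_phase",
    "instantaneous_frequency",
]


class ShortSegmentError(ValueError):
    """The segment is too short for two-pass filtering at this order."""


@dataclass(frozen=True)
class BandSpec:
    """Band-pass specification.

    ``order`` is the FIR filter order (even, so the group delay is an
    integer number of samples). When None the order defaults to three
    cycles of the low cutoff, ``3 * fs / low`` — the convention of the
    standard M/EEG preprocessing toolchains — reduced automatically when
    a segment is too short for forward-backward application. Short
    real-time windows therefore get a weaker filter than full offline
    records; that asymmetry is intrinsic to causal, window-based
    processing.
    """

    low: float = 8.0
    high: float = 12.0
    order: Optional[int] = None

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.order is not None and (self.order <= 0 or self.order % 2):
            raise ValueError("order must be a positive even integer")

    def resolve_order(self, n_samples: int, fs: float) -> int:
        if self.high >= fs / 2.0:
            raise ValueError("band high edge must be below the Nyquist frequency")
        order = self.order if self.order is not None else int(3 * fs / self.low)
        order -= order % 2
        # filtfilt needs n > 3 * ntaps (default pad length)
        cap = (n_samples - 1) // 3 - 1
        cap -= cap % 2
        if self.order is None:
            order = min(order, cap)
        if order > cap or order < 2:
            need = 3 * (order + 1) + 1
            raise ShortSegmentError(
                f"segment of {n_samples} samples is too short for two-pass "
                f"FIR order {order}; at least {need} samples are required"
            )
        return order

    def design(self, n_samples: int, fs: float) -> np.ndarray:
        order = self.resolve_order(n_samples, fs)
        return firwin(order + 1, [self.low, self.high], pass_zero=False,
                      window="hamming", fs=fs)


@dataclass
class AnalyticSeries:
    """Per-sample phase (deg, wrapped) and non-negative envelope."""

    phase: np.ndarray
    amplitude: np.ndarray
    fs: float


def fir_bandpass_zero_phase(samples, band: BandSpec, fs, *, axis=-1,
                            causal: bool = False):
    """Zero-phase band-pass filter (forward-backward linear-phase FIR).

    With ``causal=True`` the filter is applied in a single forward pass
    with integer group-delay compensation by shifting, for
    strict-causality experiments; the default two-pass application has
    exactly zero phase shift at every frequency.
    """
    x = np.asarray(samples, dtype=float)
    taps = band.design(x.shape[axis], fs)
    if causal:
        y = lfilter(taps, 1.0, x, axis=axis)
        return np.roll(y, -(len(taps) // 2), axis=axis)
    return filtfilt(taps, 1.0, x, axis=axis)


def analytic_phase(filtered_samples, fs, *, axis=-1) -> AnalyticSeries:
    """Instantaneous phase and envelope via the analytic signal.

    On a pure cosine ``a cos(2 pi f t)`` the phase crosses 0 deg at the
    signal maxima (cosine convention) and the envelope approximates
    ``a`` away from the record edges.
    """
    x = np.asarray(filtered_samples, dtype=float)
    if x.size == 0:
        raise ValueError("analytic_phase requires a non-empty series")
    z = hilbert(x, axis=axis)
    return AnalyticSeries(
        phase=wrap_angle(np.rad2deg(np.angle(z))),
        amplitude=np.abs(z),
        fs=fs,
    )


def instantaneous_frequency(phase_series_deg, fs, median_window_ms=10.0):
    """Instantaneous frequency (Hz) from a wrapped phase series.

    The phase is unwrapped, differentiated (one-sided at the record
    boundaries) and scaled by ``fs / 360``; a moving median over
    ``median_window_ms`` rejects single-sample phase glitches without
    distorting smooth frequency trajectories.
    """
    phase = np.asarray(phase_series_deg, dtype=float)
    if phase.size < 2:
        raise ValueError("instantaneous_frequency requires >= 2 samples")
    win = int(round(median_window_ms * fs / 1000.0))
    if win < 1:
        raise ValueError("median window must span at least one sample")
    unwrapped = np.unwrap(phase, period=360.0)
    if_hz = np.gradient(unwrapped) * fs / 360.0
    if win > 1:
        if_hz = median_filter(if_hz, size=win, mode="nearest")
    return if_hz
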