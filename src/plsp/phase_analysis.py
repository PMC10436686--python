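"""Offline statistics for phase-locked experiments.

Cosine-similarity intertrial phase coherence (unbiased by trial count),
cut-and-swap surrogate nulls, jackknife fractional-peak latency
estimation, and FFT-initialized sinusoid fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .circstats import wrap_angle
from .sigproc import BandSpec, analytic_phase, fir_bandpass_zero_phase

__all__ = [
    "SurrogateNull",
    "SinusoidFit",
    "NoCrossingError",
    "FitFailureError",
    "itc_cs",
    "itc_cs_timecourse",
    "phases_from_trials",
    "surrogate_itc_null",
    "jackknife_latency",
    "fit_sinusoid",
    "sine_phase_to_cosine",
]


class NoCrossingError(ValueError):
    """A leave-one-out waveform never crosses the fractional threshold."""


class FitFailureError(RuntimeError):
    """Nonlinear fit did not converge; carries the initial values."""

    def __init__(self, p0):
        self.initial_values = p0
        super().__init__(f"sinusoid fit failed to converge from initial values {p0}")


# ------------------------------------------------------------ ITC_CS


def itc_cs(angles_deg) -> float:
    """Cosine-similarity intertrial phase coherence.

    The mean cosine of the phase differences over all trial pairs,
    ``2 / (N (N-1)) * sum_{i<j} cos(theta_i - theta_j)``, computed via
    the closed-form identity ``(|sum exp(i theta)|^2 - N) / (N (N-1))``.
    1 means all trials share one phase, 0 a uniform spread; values are
    negative when phases sit on average more than 90 deg apart. Unlike
    the resultant-length coherence this estimator is unbiased in N.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 2:
        raise ValueError("itc_cs requires at least two trials")
    z = np.exp(1j * np.deg2rad(a))
    return float((abs(z.sum()) ** 2 - n) / (n * (n - 1)))


def itc_cs_timecourse(angles_deg: np.ndarray) -> np.ndarray:
    """ITC_CS at every time point of a trials x samples angle matrix."""
    a = np.asarray(angles_deg, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need a 2-D trials x samples matrix with >= 2 trials")
    n = a.shape[0]
    s = np.exp(1j * np.deg2rad(a)).sum(axis=0)
    return (np.abs(s) ** 2 - n) / (n * (n - 1))


def phases_from_trials(trials: np.ndarray, band, fs,
                       fir_order: Optional[int] = None) -> np.ndarray:
    """Filter-Hilbert phase matrix (deg) from raw trials x samples data."""
    x = np.asarray(trials, dtype=float)
    if x.ndim != 2:
        raise ValueError("trials must be a 2-D trials x samples array")
    spec = BandSpec(band[0], band[1], order=fir_order)
    filtered = fir_bandpass_zero_phase(x, spec, fs, axis=1)
    return analytic_phase(filtered, fs, axis=1).phase


@dataclass
class SurrogateNull:
    """Surrogate ITC_CS distribution per time point and its mean (chance)."""

    values: np.ndarray  # n_rep x n_samples
    chance: np.ndarray  # n_samples
    n_rep: int
    seed: int


def surrogate_itc_null(trial_series: np.ndarray, band, fs, n_rep=1000,
                       seed=0, fir_order: Optional[int] = None) -> SurrogateNull:
    """Cut-and-swap surrogate null for the ITC_CS time course.

    Each repetition cuts every raw trial at an independent uniform
    random sample and swaps the two sections (a circular rotation that
    preserves the sample distribution and the phase dynamics while
    destroying the alignment to the event), re-extracts phases by the
    same filter-Hilbert path, and recomputes ITC_CS at every time
    point. The chance level is the mean over repetitions.
    """
    x = np.asarray(trial_series, dtype=float)
    if x.ndim != 2:
        raise ValueError("trial_series must be a trials x samples array "
                         "(equal-length trials)")
    n_trials, n_samp = x.shape
    if n_samp < 2:
        raise ValueError("trials must contain at least two samples")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.arange(n_trials)[:, None]
    values = np.empty((n_rep, n_samp))
    for rep in range(n_rep):
        cuts = rng.integers(0, n_samp, size=n_trials)
        idx = (np.arange(n_samp)[None, :] + cuts[:, None]) % n_samp
        rotated = x[rows, idx]
        angles = phases_from_trials(rotated, band, fs, fir_order=fir_order)
        values[rep] = itc_cs_timecourse(angles)
    return SurrogateNull(values=values, chance=values.mean(axis=0),
                         n_rep=n_rep, seed=seed)


# --------------------------------------------------------- jackknife


def _fractional_crossing(wave: np.ndarray, fraction: float, mode: str) -> float:
    """Sub-sample index where |wave| crosses fraction * peak."""
    rect = np.abs(wave)
    peak = rect.max()
    if peak <= 0:
        raise NoCrossingError("waveform is identically zero in the window")
    thr = fraction * peak
    above = rect >= thr
    if mode == "onset":
        if above[0]:
            raise NoCrossingError(
                "waveform already exceeds the threshold at the window start")
        i = int(np.argmax(above))
        return (i - 1) + (thr - rect[i - 1]) / (rect[i] - rect[i - 1])
    if mode == "offset":
        if above[-1]:
            raise NoCrossingError(
                "waveform still exceeds the threshold at the window end")
        j = len(rect) - 1 - int(np.argmax(above[::-1]))
        return j + (rect[j] - thr) / (rect[j] - rect[j + 1])
    raise ValueError("mode must be 'onset' or 'offset'")


def jackknife_latency(waveforms: np.ndarray, fs, fraction=0.3, mode="onset",
                      search_window=None, t0_sample=0) -> float:
    """Leave-one-out fractional-peak latency, in ms relative to ``t0_sample``.

    For each of the N leave-one-out grand averages, the first (onset)
    or last (offset) crossing of ``fraction`` of the rectified peak
    within ``search_window`` (a ``(start_ms, stop_ms)`` pair relative to
    ``t0_sample``; default the whole record) is found with linear
    interpolation between samples; the mean of the N estimates is
    returned.
    """
    w = np.asarray(waveforms, dtype=float)
    if w.ndim != 2 or w.shape[0] < 2:
        raise ValueError("need >= 2 subjects in a subjects x samples array")
    n_subj, n_samp = w.shape
    if search_window is None:
        lo, hi = 0, n_samp
    else:
        lo = t0_sample + int(round(search_window[0] * fs / 1000.0))
        hi = t0_sample + int(round(search_window[1] * fs / 1000.0)) + 1
        if not 0 <= lo < hi <= n_samp:
            raise ValueError("search window outside the record")
    total = w.sum(axis=0)
    estimates = []
    for i in range(n_subj):
        avg = (total - w[i]) / (n_subj - 1)
        try:
            cross = _fractional_crossing(avg[lo:hi], fraction, mode)
        except NoCrossingError as exc:
            raise NoCrossingError(
                f"leave-one-out subsample omitting subject {i}: {exc}") from exc
        estimates.append(lo + cross)
    mean_idx = float(np.mean(estimates))
    return (mean_idx - t0_sample) * 1000.0 / fs


# ---------------------------------------------------------- sinusoid


@dataclass
class SinusoidFit:
    """Least-squares fit of ``y(t) = a sin(2 pi f t + phi) + b``.

    ``phi`` is in degrees, sine convention (use
    :func:`sine_phase_to_cosine` for the toolkit's cosine convention);
    ``a`` is non-negative (sign absorbed into ``phi``).
    """

    a: float
    f: float
    phi_deg: float
    b: float
    rss: float
    r_squared: float


def sine_phase_to_cosine(phi_sine_deg: float) -> float:
    """Convert a sine-convention phase to the cosine convention."""
    return wrap_angle(phi_sine_deg - 90.0)


def fit_sinusoid(y, fs) -> SinusoidFit:
    """Fit a single sinusoid by FFT-initialized nonlinear least squares.

    The offset starts at the sample mean; frequency, amplitude and
    phase start from the dominant non-DC Fourier component; then all
    four parameters are refined by least squares. A constant input
    returns amplitude 0 with ``r_squared`` defined as 0.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 8:
        raise ValueError("fit_sinusoid requires at least 8 samples")
    b0 = float(y.mean())
    yc = y - b0
    tss = float(np.sum(yc ** 2))
    if np.std(yc) < 1e-12 * max(1.0, abs(b0)):
        return SinusoidFit(a=0.0, f=0.0, phi_deg=0.0, b=b0, rss=tss, r_squared=0.0)
    spec = np.fft.rfft(yc)
    k = 1 + int(np.argmax(np.abs(spec[1:])))
    f0 = k * fs / n
    a0 = 2.0 * abs(spec[k]) / n
    # cosine-coefficient angle -> sine convention: sin(x + 90) = cos(x)
    phi0 = np.angle(spec[k]) + np.pi / 2.0
    t = np.arange(n) / fs

    def model(t, a, f, phi, b):
        return a * np.sin(2.0 * np.pi * f * t + phi) + b

    p0 = (a0, f0, phi0, b0)
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(p0) from exc
    a, f, phi, b = popt
    if a < 0:
        a, phi = -a, phi + np.pi
    if f < 0:
        f, phi = -f, np.pi - phi
    rss = float(np.sum((y - model(t, a, f, phi, b)) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return SinusoidFit(a=float(a), f=float(f),
                       phi_deg=wrap_angle(np.rad2deg(phi)),
                       b=float(b), rss=rss, r_squared=float(r2))
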