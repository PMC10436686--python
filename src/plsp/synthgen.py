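"""Synthetic inputs with analytic ground truth.

Everything the rest of the toolkit is validated on is produced here:
band-limited oscillations whose exact phase track is known in closed
form, white noise scaled to an exact signal-to-noise ratio, angular
trial sets for coherence statistics, and a simulated psychophysical
observer driving an adaptive staircase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .circstats import wrap_angle

__all__ = [
    "SyntheticTrace",
    "ObserverModel",
    "StaircaseResult",
    "gen_oscillation",
    "gen_drifting_oscillation",
    "add_noise_at_snr",
    "gen_phase_trials",
    "simulate_staircase",
]


@dataclass
class SyntheticTrace:
    """A single-channel time series with optional analytic ground truth.

    ``true_phase`` holds per-sample phase in degrees wrapped to
    [-180, 180) in the cosine convention (0 deg at positive peaks);
    ``true_freq`` the per-sample frequency in Hz. Both are None for
    traces without analytic truth (e.g. loaded recordings).
    """

    samples: np.ndarray
    fs: float
    true_phase: Optional[np.ndarray] = None
    true_freq: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.true_phase is not None:
            self.true_phase = np.asarray(self.true_phase, dtype=float)
            if len(self.true_phase) != len(self.samples):
                raise ValueError("true_phase must match samples in length")
        if self.true_freq is not None:
            self.true_freq = np.asarray(self.true_freq, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


def _resolve_freq(freq_spec, fs: float, rng: np.random.Generator) -> float:
    if np.isscalar(freq_spec):
        f = float(freq_spec)
    else:
        low, high = (float(v) for v in freq_spec)
        if not 0.0 < low <= high:
            raise ValueError("frequency band must satisfy 0 < low <= high")
        f = float(rng.uniform(low, high))
    if not 0.0 < f < fs / 2.0:
        raise ValueError(
            f"frequency {f} Hz violates the open Nyquist interval (0, {fs / 2}) Hz"
        )
    return f


def gen_oscillation(duration_s, fs, freq_spec, seed=0, phi0_deg=0.0):
    """Generate a pure cosine oscillation with analytic phase truth.

    ``freq_spec`` is either a fixed frequency in Hz or a ``(low, high)``
    band from which one frequency is drawn uniformly per realization
    (one tone for the whole trace, so ground truth stays analytic).
    The phase track is ``wrap(360 f t + phi0)`` and the samples are
    ``cos`` of it; at ``phi0 = 0`` every local maximum sits exactly at
    phase 0. Deterministic given ``seed``.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = np.random.default_rng(seed)
    f = _resolve_freq(freq_spec, fs, rng)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    phase_unwrapped = 360.0 * f * t + phi0_deg
    samples = np.cos(np.deg2rad(phase_unwrapped))
    return SyntheticTrace(
        samples=samples,
        fs=fs,
        true_phase=wrap_angle(phase_unwrapped),
        true_freq=np.full(n, f),
        seed=seed,
    )


def gen_drifting_oscillation(duration_s, fs, band=(8.0, 12.0), seed=0,
                             drift_sd_hz=0.02, phi0_deg=0.0):
    """Oscillation whose frequency performs a slow random walk in a band.

    A robustness variant for non-stationary rhythms: the instantaneous
    frequency starts at a uniform draw inside ``band`` and takes
    Gaussian steps of SD ``drift_sd_hz`` per sample, reflected at the
    band edges. The phase is the cumulative integral of the frequency,
    so ground truth remains exact.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    low, high = (float(v) for v in band)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    steps = rng.normal(0.0, drift_sd_hz, size=n)
    f0 = rng.uniform(low, high)
    freq = f0 + np.cumsum(steps)
    # reflect the walk into [low, high]
    span = high - low
    freq = low + np.abs((freq - low) % (2 * span) - span)
    phase_unwrapped = phi0_deg + 360.0 * np.concatenate(([0.0], np.cumsum(freq[:-1]) / fs))
    samples = np.cos(np.deg2rad(phase_unwrapped))
    return SyntheticTrace(
        samples=samples, fs=fs,
        true_phase=wrap_angle(phase_unwrapped),
        true_freq=freq, seed=seed,
    )


def add_noise_at_snr(trace: SyntheticTrace, snr_linear: float, seed=0) -> SyntheticTrace:
    """Add white Gaussian noise at an exact linear SNR.

    The SNR is the ratio of summed squared signal magnitude to that of
    the noise; the realized noise is rescaled so the ratio is exact
    (snr_linear = 1 means equal signal and noise energy, i.e. 0 dB).
    Ground-truth tracks are carried over unchanged.
    """
    if snr_linear <= 0:
        raise ValueError("snr_linear must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(trace.samples))
    sig_energy = float(np.sum(trace.samples ** 2))
    noise_energy = float(np.sum(noise ** 2))
    if noise_energy > 0:
        noise *= np.sqrt(sig_energy / (snr_linear * noise_energy))
    return SyntheticTrace(
        samples=trace.samples + noise,
        fs=trace.fs,
        true_phase=None if trace.true_phase is None else trace.true_phase.copy(),
        true_freq=None if trace.true_freq is None else trace.true_freq.copy(),
        seed=seed,
    )


def gen_phase_trials(n_trials, distribution, params=None, seed=0):
    """Draw a set of trial phase angles in degrees, wrapped to [-180, 180).

    ``distribution`` is one of ``"uniform"``, ``"von_mises"`` (params:
    ``mu_deg``, ``kappa``) or ``"fixed_set"`` (params: ``angles``, cycled
    to length ``n_trials``).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or {}
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        angles = rng.uniform(-180.0, 180.0, size=n_trials)
    elif distribution == "von_mises":
        mu = np.deg2rad(params.get("mu_deg", 0.0))
        kappa = params.get("kappa", 1.0)
        angles = np.rad2deg(rng.vonmises(mu, kappa, size=n_trials))
    elif distribution == "fixed_set":
        base = np.asarray(params["angles"], dtype=float)
        angles = np.resize(base, n_trials)
    else:
        raise ValueError(f"unknown distribution: {distribution!r}")
    return wrap_angle(angles)


@dataclass
class ObserverModel:
    """Simulated observer with a logistic psychometric function.

    Detection probability is ``expit(slope * (level - threshold))``:
    strictly increasing in the stimulus level, exactly 0.5 at
    ``threshold``. A very large slope approximates a deterministic
    step observer.
    """

    threshold: float
    slope: float
    seed: int = 0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")

    def p_detect(self, level) -> np.ndarray:
        return expit(self.slope * (np.asarray(level, dtype=float) - self.threshold))


@dataclass
class StaircaseResult:
    levels: np.ndarray
    responses: np.ndarray            # True = detect
    reversal_indices: np.ndarray     # trial indices where step direction changed
    converged_level: float

    @property
    def reversal_levels(self) -> np.ndarray:
        return self.levels[self.reversal_indices]


def simulate_staircase(observer: ObserverModel, start_level, step,
                       max_reversals=5, seed=0, max_trials=None) -> StaircaseResult:
    """Run a one-up, one-down fixed-step staircase against an observer.

    The level decreases by ``step`` after each detection and increases
    by ``step`` after each miss, so the procedure converges to the 50%
    point of the psychometric function. A reversal is a trial on which
    the step direction changes relative to the previous trial. The run
    terminates when ``max_reversals`` reversals have occurred (pass
    ``max_reversals=None`` with a finite ``max_trials`` to disable
    termination). ``converged_level`` is the mean of the reversal
    levels.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if max_reversals is None and max_trials is None:
        raise ValueError("either max_reversals or max_trials must be finite")
    if max_reversals is not None and max_reversals < 1:
        raise ValueError("max_reversals must be >= 1")
    rng = np.random.default_rng(seed)
    level = float(start_level)
    levels, responses, reversals = [], [], []
    prev_direction = None  # -1 after detect (down), +1 after miss (up)
    trial = 0
    while True:
        if max_trials is not None and trial >= max_trials:
            break
        detected = bool(rng.random() < observer.p_detect(level))
        levels.append(level)
        responses.append(detected)
        direction = -1 if detected else +1
        if prev_direction is not None and direction != prev_direction:
            reversals.append(trial)
        prev_direction = direction
        level += direction * step
        trial += 1
        if max_reversals is not None and len(reversals) >= max_reversals:
            break
    levels = np.asarray(levels)
    reversals = np.asarray(reversals, dtype=int)
    converged = float(levels[reversals].mean()) if len(reversals) else float("nan")
    return StaircaseResult(
        levels=levels,
        responses=np.asarray(responses, dtype=bool),
        reversal_indices=reversals,
        converged_level=converged,
    )
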