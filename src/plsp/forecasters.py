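"""Causal phase/instantaneous-frequency forecasters.

Three estimators share one contract: given the most recent band-pass
filtered analysis window ending at the current sample, return the phase
(deg) and instantaneous frequency (Hz) at that sample.

- ``ar_estimate``: trims the window edges, fits an autoregressive model
  (Yule-Walker coefficients, BIC order selection), forward-predicts
  past the window end and reads the analytic phase at the current
  sample from the extended segment. Forward prediction moves the
  current sample away from the analytic-transform edge, where the
  Hilbert phase is distorted.
- ``fft_estimate``: zero-pads the window, picks the dominant spectral
  component and projects its phase forward to the current sample.
- ``akf_estimate``: runs an adaptive Kalman filter on the state
  [phase, frequency] over the last half oscillation cycle, fusing the
  noisy measured analytic phase with a constant-frequency prediction;
  the covariance-inflation factor alpha drops below one whenever the
  measured frequency leaves the band, down-weighting edge-distorted or
  noise-corrupted measurements.

``delay_to_phase`` converts an estimate into the forward delay (in
samples) to the next occurrence of a desired phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from statsmodels.tsa.stattools import acovf, levinson_durbin

from .circstats import wrap_angle
from .sigproc import analytic_phase

__all__ = [
    "PhaseEstimate",
    "KalmanParams",
    "KalmanState",
    "ShortWindowError",
    "DegenerateWindowError",
    "ARInstabilityError",
    "NoDominantComponentError",
    "InvalidStateError",
    "InvalidEstimateError",
    "select_ar_order",
    "ar_estimate",
    "fft_estimate",
    "kf_predict",
    "kf_update",
    "akf_estimate",
    "delay_to_phase",
    "ESTIMATORS",
]

DEG_PER_MS_TO_HZ = 1000.0 / 360.0
IF_FLOOR_HZ = 1e-3


class ShortWindowError(ValueError):
    """Analysis window too short for the estimator."""


class DegenerateWindowError(ValueError):
    """Window carries no usable signal (e.g. all zeros)."""


class ARInstabilityError(RuntimeError):
    """Forward prediction diverged; carries the selected model order."""

    def __init__(self, order: int):
        self.order = order
        super().__init__(f"AR forward prediction diverged (selected order {order})")


class NoDominantComponentError(ValueError):
    """Spectrum has no usable dominant component."""


class InvalidStateError(ValueError):
    """Kalman state covariance is not symmetric positive semidefinite."""


class InvalidEstimateError(ValueError):
    """Estimate cannot be used (non-positive or flagged frequency)."""


@dataclass
class PhaseEstimate:
    """Forecaster output at the current sample.

    ``flagged`` marks estimates whose frequency had to be clamped to a
    small positive floor (possible under heavy noise); the real-time
    loop refuses flagged estimates and waits for the next chunk.
    """

    phase_deg: float
    if_hz: float
    at_sample: int
    algorithm: str
    flagged: bool = False


def _finalize(phase_deg, if_hz, at_sample, algorithm) -> PhaseEstimate:
    flagged = not np.isfinite(if_hz) or if_hz <= 0
    if flagged:
        if_hz = IF_FLOOR_HZ
    return PhaseEstimate(
        phase_deg=wrap_angle(float(phase_deg)),
        if_hz=float(if_hz),
        at_sample=int(at_sample),
        algorithm=algorithm,
        flagged=flagged,
    )


# ---------------------------------------------------------------- AR


def select_ar_order(x, max_order=30, min_order=2) -> Tuple[int, np.ndarray]:
    """BIC order selection over Yule-Walker fits.

    One Levinson-Durbin recursion yields the Yule-Walker coefficients
    for every candidate order at once; each candidate is scored by the
    BIC of its empirical one-step prediction residuals, evaluated on
    the common sample span t = max_order .. n-1 so all candidates are
    compared on identical data. Returns the winning order and its
    coefficient vector.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 * max_order:
        raise ShortWindowError(
            f"{n} samples cannot support AR order selection up to {max_order}"
        )
    # Biased autocovariance without mean removal (the aryule convention):
    # band-passed input is zero-mean by construction, and demeaning a
    # non-integer number of cycles badly distorts short-window fits.
    acov = acovf(x, nlag=max_order, adjusted=False, demean=False, fft=True)
    _, _, _, _, phi = levinson_durbin(acov, nlags=max_order, isacov=True)
    ne = n - max_order
    # lagged design matrix: column k-1 holds x_{t-k} for t in the span
    lags = np.column_stack([x[max_order - k:n - k] for k in range(1, max_order + 1)])
    target = x[max_order:]
    best = None
    log_ne = np.log(ne)
    for p in range(min_order, max_order + 1):
        c = phi[1:p + 1, p]
        resid = target - lags[:, :p] @ c
        sig2 = max(float(np.mean(resid ** 2)), np.finfo(float).tiny)
        bic = ne * np.log(sig2) + p * log_ne
        if best is None or bic < best[0]:
            best = (bic, p, c)
    return best[1], best[2].copy()


def ar_estimate(window_samples, fs, band=(8.0, 12.0), *, at_sample=None,
                trim_ms=75.0, max_order=30) -> PhaseEstimate:
    """Autoregressive forward-prediction phase estimate.

    The filtered window is trimmed by ``trim_ms`` at both ends (the
    filter and analytic-transform edges), an AR model is fitted to the
    remaining segment and iterated forward one step at a time until
    ``trim_ms`` past the current sample. The analytic phase of the
    concatenated (trimmed + predicted) segment is read at the current
    sample, which now lies well inside the record.
    """
    x = np.asarray(window_samples, dtype=float)
    n = len(x)
    trim = int(round(trim_ms * fs / 1000.0))
    if n <= 2 * trim + max_order + 1:
        raise ShortWindowError(
            f"window of {n} samples too short for {trim_ms} ms edge trimming "
            f"plus AR fitting (need > {2 * trim + max_order + 1})"
        )
    core = x[trim:n - trim]
    if np.std(core) < 1e-12:
        raise DegenerateWindowError("window is constant; no oscillation to model")
    p, coeffs = select_ar_order(core, max_order=max_order)
    n_pred = 2 * trim  # through t_current + trim_ms
    buf = np.concatenate([core, np.zeros(n_pred)])
    m = len(core)
    for i in range(n_pred):
        buf[m + i] = np.dot(coeffs, buf[m + i - 1:m + i - 1 - p:-1])
    if not np.all(np.isfinite(buf)):
        raise ARInstabilityError(p)
    extended = buf
    series = analytic_phase(extended, fs)
    idx = m + trim - 1  # position of t_current in the extended segment
    unwrapped = np.unwrap(series.phase, period=360.0)
    if_hz = np.gradient(unwrapped) * fs / 360.0
    if at_sample is None:
        at_sample = n - 1
    return _finalize(series.phase[idx], if_hz[idx], at_sample, "AR")


# --------------------------------------------------------------- FFT


def fft_estimate(window_samples, fs, pad_to=1800, *, at_sample=None) -> PhaseEstimate:
    """Dominant-component projection phase estimate.

    The window is zero-padded to ``pad_to`` points for finer frequency
    resolution; the maximum-power bin defines the dominant frequency
    (ties break toward the lower frequency), whose phase — referenced
    to the first window sample — is projected forward to the current
    sample at that single frequency.
    """
    x = np.asarray(window_samples, dtype=float)
    n = len(x)
    if pad_to < n:
        raise ValueError("pad_to must be >= the window length")
    if n == 0 or np.max(np.abs(x)) == 0.0:
        raise NoDominantComponentError("window is all zero; no dominant component")
    spec = np.fft.rfft(x, n=pad_to)
    power = np.abs(spec)
    # ties (within float tolerance) break toward the lower frequency
    k = int(np.argmax(power >= power.max() * (1.0 - 1e-9)))
    f_dom = k * fs / pad_to
    phase_first = np.rad2deg(np.angle(spec[k]))
    phase_tc = phase_first + 360.0 * f_dom * (n - 1) / fs
    if at_sample is None:
        at_sample = n - 1
    return _finalize(phase_tc, f_dom, at_sample, "FFT")


# --------------------------------------------------------------- AKF


def _default_Q() -> np.ndarray:
    return np.zeros((2, 2))


@dataclass
class KalmanParams:
    """Fixed noise and adaptation parameters of the adaptive filter.

    Units: the state is [phase (deg, unwrapped), frequency (deg/ms)].
    ``r`` is the measurement noise variance of the analytic phase of
    band-pass filtered data at SNR 1 (93 deg SD); ``r0`` initializes the
    phase variance to the same value; ``xdot_max`` = 4.32 deg/ms is the
    velocity of the 12 Hz band edge, and its square initializes the
    frequency variance. ``q`` (process noise) stays zero: within a
    300 ms window the frequency is locally constant. ``alpha`` inflates
    the predicted covariance; it is nominally 1 and drops to 0.8 when
    the measured frequency leaves the band, shrinking the Kalman gain
    so the prediction dominates over a suspect measurement.
    """

    r: float = 93.0 ** 2
    r0: float = 93.0 ** 2
    xdot_max: float = 4.32
    q: np.ndarray = field(default_factory=_default_Q)
    alpha_nominal: float = 1.0
    alpha_oob: float = 0.8
    band: Tuple[float, float] = (8.0, 12.0)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.r <= 0:
            raise ValueError("measurement variance r must be positive")
        if not 0 < self.alpha_oob <= self.alpha_nominal:
            raise ValueError("need 0 < alpha_oob <= alpha_nominal")


@dataclass
class KalmanState:
    """State mean x = [phase (deg, unwrapped), frequency (deg/ms)] and covariance P."""

    x: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float).reshape(2)
        self.P = np.asarray(self.P, dtype=float).reshape(2, 2)


def _check_psd(P: np.ndarray, tol=1e-9) -> None:
    if abs(P[0, 1] - P[1, 0]) > tol * (1.0 + abs(P[0, 1])):
        raise InvalidStateError("covariance is not symmetric")
    det = P[0, 0] * P[1, 1] - P[0, 1] * P[1, 0]
    if P[0, 0] < -tol or P[1, 1] < -tol or det < -tol * (1.0 + P[0, 0] * P[1, 1]):
        raise InvalidStateError("covariance is not positive semidefinite")


def kf_predict(state: KalmanState, dt_ms: float, alpha: float,
               params: KalmanParams) -> KalmanState:
    """Constant-frequency prediction: x <- F x, P <- alpha^2 F P F' + Q.

    F = [[1, dt], [0, 1]] advances the phase by frequency * dt; no
    acceleration term, as the frequency is assumed locally constant.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    _check_psd(state.P)
    x0, x1 = state.x
    p00, p01, p11 = state.P[0, 0], state.P[0, 1], state.P[1, 1]
    a2 = alpha * alpha
    q = params.q
    nx = np.array([x0 + dt_ms * x1, x1])
    n00 = a2 * (p00 + dt_ms * (2.0 * p01 + dt_ms * p11)) + q[0, 0]
    n01 = a2 * (p01 + dt_ms * p11) + q[0, 1]
    n11 = a2 * p11 + q[1, 1]
    return KalmanState(nx, np.array([[n00, n01], [n01, n11]]))


def kf_update(state: KalmanState, z_phase_deg: float,
              params: KalmanParams) -> KalmanState:
    """Measurement update with wrapped innovation and Joseph-form covariance.

    The measurement is the analytic phase (H = [1, 0]); the innovation
    ``y = z - H x`` is wrapped to [-180, 180) so the linear update
    respects circularity. The Joseph form
    ``(I - K H) P (I - K H)' + K R K'`` keeps P symmetric PSD.
    """
    _check_psd(state.P)
    p00, p01, p11 = state.P[0, 0], state.P[0, 1], state.P[1, 1]
    s = p00 + params.r
    if s <= 0:
        raise InvalidStateError("singular innovation covariance")
    k0 = p00 / s
    k1 = p01 / s
    y = wrap_angle(float(z_phase_deg) - state.x[0])
    nx = np.array([state.x[0] + k0 * y, state.x[1] + k1 * y])
    a = 1.0 - k0
    r = params.r
    n00 = a * a * p00 + r * k0 * k0
    n01 = a * (p01 - k1 * p00) + r * k0 * k1
    n11 = k1 * k1 * p00 - 2.0 * k1 * p01 + p11 + r * k1 * k1
    return KalmanState(nx, np.array([[n00, n01], [n01, n11]]))


def akf_estimate(window_samples, fs, band=(8.0, 12.0), params=None, *,
                 at_sample=None) -> PhaseEstimate:
    """Adaptive-Kalman-filter phase estimate at the window's last sample.

    The filter re-initializes half a nominal oscillation cycle (at the
    band center) before the current sample from the measured analytic
    phase and frequency, with P = diag(r0, xdot_max^2), then runs
    per-sample predict/update to the window end. At each step the
    measured one-sample frequency decides alpha: out-of-band
    measurements (noise, analytic-transform edge distortion) get
    alpha_oob < 1, which deflates the predicted covariance and thus the
    Kalman gain.
    """
    if params is None:
        params = KalmanParams(band=tuple(band))
    x = np.asarray(window_samples, dtype=float)
    n = len(x)
    fc = 0.5 * (band[0] + band[1])
    n_half = int(round(fs / (2.0 * fc)))
    if n < n_half + 2:
        raise ShortWindowError(
            f"window of {n} samples shorter than half a {fc} Hz cycle + 1"
        )
    if np.max(np.abs(x)) == 0.0:
        raise DegenerateWindowError("window is all zero")
    meas = np.unwrap(analytic_phase(x, fs).phase, period=360.0)
    dt_ms = 1000.0 / fs
    start = n - 1 - n_half
    if0 = (meas[start + 1] - meas[start]) / dt_ms if start + 1 < n else 0.0
    state = KalmanState(
        x=np.array([meas[start], if0]),
        P=np.array([[params.r0, 0.0], [0.0, params.xdot_max ** 2]]),
    )
    lo, hi = band
    for t in range(start + 1, n):
        if_meas_hz = (meas[t] - meas[t - 1]) / dt_ms * DEG_PER_MS_TO_HZ
        alpha = params.alpha_nominal if lo <= if_meas_hz <= hi else params.alpha_oob
        state = kf_predict(state, dt_ms, alpha, params)
        state = kf_update(state, meas[t], params)
    if at_sample is None:
        at_sample = n - 1
    return _finalize(state.x[0], state.x[1] * DEG_PER_MS_TO_HZ, at_sample, "AKF")


# ------------------------------------------------------------- delay


def delay_to_phase(estimate: PhaseEstimate, desired_phase_deg: float, fs: float) -> int:
    """Samples until the oscillation next reaches the desired phase.

    ``round(fs * dphi / (360 * IF))`` with the phase advance ``dphi``
    wrapped into [0, 360); the result lies in [0, fs / IF) (one
    oscillation period).
    """
    if estimate.flagged or estimate.if_hz <= 0:
        raise InvalidEstimateError(
            "estimate has non-positive or flagged instantaneous frequency"
        )
    dphi = (float(desired_phase_deg) - estimate.phase_deg) % 360.0
    period = fs / estimate.if_hz
    delay = int(round(fs * dphi / (360.0 * estimate.if_hz)))
    if delay >= period:
        delay = 0
    return delay


ESTIMATORS = {
    "AR": ar_estimate,
    "FFT": fft_estimate,
    "AKF": akf_estimate,
}
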