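"""Minimal circular-statistics kernel shared by every module.

All angles are degrees. The toolkit-wide convention is the cosine
convention: 0 deg at the positive peak of an oscillation, increasing
with time, wrapped to the half-open interval [-180, 180).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "circ_abs_distance",
    "circ_mean",
    "circ_sd",
]


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be finite")


def wrap_angle(x_deg):
    """Wrap angle(s) into [-180, 180).

    180 maps to -180 (half-open convention, deterministic at the
    boundary). Accepts scalars or arrays; returns the same shape.
    """
    x = np.asarray(x_deg, dtype=float)
    _check_finite(x, "angle")
    w = (x + 180.0) % 360.0 - 180.0
    if np.isscalar(x_deg) or x.ndim == 0:
        return float(w)
    return w


def circ_abs_distance(a_deg, b_deg):
    """Shortest angular distance |a - b| on the circle, in [0, 180]."""
    a = np.asarray(a_deg, dtype=float)
    b = np.asarray(b_deg, dtype=float)
    _check_finite(a, "a_deg")
    _check_finite(b, "b_deg")
    d = np.abs(a - b) % 360.0
    d = np.minimum(d, 360.0 - d)
    if d.ndim == 0:
        return float(d)
    return d


def circ_mean(angles_deg):
    """Circular mean direction and resultant length.

    Returns ``(mean_deg, r)`` where ``mean_deg = arg sum(exp(i theta))``
    wrapped to [-180, 180) and ``r = |sum(exp(i theta))| / n`` in [0, 1].
    When the resultant is numerically zero (r < 1e-12) the mean
    direction is undefined and returned as NaN; r is still returned.
    """
    a = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("circ_mean requires at least one angle")
    _check_finite(a, "angles")
    rad = np.deg2rad(a)
    z = np.exp(1j * rad).mean()
    r = min(float(np.abs(z)), 1.0)  # guard rounding above 1
    if r < 1e-12:
        return float("nan"), r
    return wrap_angle(np.rad2deg(np.angle(z))), r


def circ_sd(angles_deg, *, definition: str = "angular"):
    """Circular standard deviation, in degrees.

    Two standard definitions are exposed:

    - ``"angular"`` (default): sqrt(2 (1 - r)) radians, the angular
      deviation ``s`` of the classical circular-statistics toolboxes.
    - ``"circular"``: sqrt(-2 ln r), the circular standard deviation
      ``s0``; unbounded as r -> 0.

    Both are monotone decreasing in the resultant length r.
    """
    _, r = circ_mean(angles_deg)
    if definition == "angular":
        sd_rad = np.sqrt(2.0 * (1.0 - r))
    elif definition == "circular":
        sd_rad = np.sqrt(-2.0 * np.log(r)) if r > 0 else np.inf
    else:
        raise ValueError(f"unknown circular SD definition: {definition!r}")
    return float(np.rad2deg(sd_rad))
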