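"""Arithmetic on the 180°-periodic (axial) orientation domain.

Orientations live on the half-open interval (0, 180]; relative orientations
(signed acute differences) live on (−90, 90].  Because the domain is axial,
circular means and dispersions are computed by doubling angles onto the full
circle, averaging unit vectors, and halving back.

All public angles are in degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_orientation",
    "signed_diff",
    "circ_mean",
    "circ_sd",
    "UndefinedMeanError",
]


class UndefinedMeanError(ValueError):
    """Raised when the circular mean is undefined (zero resultant length)."""


def wrap_orientation(theta):
    """Wrap angles into the canonical orientation interval (0, 180]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.mod(theta, 180.0)
    wrapped = np.where(wrapped == 0.0, 180.0, wrapped)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def _check_orientation(theta, name):
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0.0) or np.any(theta > 180.0):
        raise ValueError(f"{name} must lie in (0, 180], got values outside range")
    return theta


def signed_diff(a, b):
    """Signed acute difference a − b on the 180°-periodic domain.

    Returns values in (−90, 90]; the boundary tie at exactly ±90° maps to
    +90°, mirroring the half-open (0, 180] convention.  Antisymmetric up to
    that boundary case.
    """
    a = _check_orientation(a, "a")
    b = _check_orientation(b, "b")
    d = np.mod(a - b, 180.0)
    d = np.where(d > 90.0, d - 180.0, d)
    if d.ndim == 0:
        return float(d)
    return d


def signed_diff_free(a, b):
    """signed_diff without the (0, 180] domain check.

    For internal use on quantities that are already relative (e.g. response
    errors, tilts around vertical) but still 180°-periodic.
    """
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 180.0)
    d = np.where(d > 90.0, d - 180.0, d)
    if d.ndim == 0:
        return float(d)
    return d


def _resultant(values, period):
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one angle")
    scale = 360.0 / period
    ang = np.deg2rad(values * scale)
    z_re = np.mean(np.cos(ang))
    z_im = np.mean(np.sin(ang))
    return z_re, z_im, scale


def circ_mean(values, period=180.0, low=None):
    """Circular mean of angles with the given period (degrees).

    Angles are doubled onto the full circle (for period 180), averaged as
    unit vectors, and the mean direction halved back.  ``low`` sets the lower
    edge of the half-open output interval ``(low, low + period]``; default is
    0 for period-180 orientations, −period/2 otherwise.

    Raises
    ------
    UndefinedMeanError
        If the resultant length is (numerically) zero, e.g. for two exactly
        perpendicular orientations.
    """
    z_re, z_im, scale = _resultant(values, period)
    r = np.hypot(z_re, z_im)
    if r < 1e-12:
        raise UndefinedMeanError("circular mean undefined: zero resultant length")
    mean = np.rad2deg(np.arctan2(z_im, z_re)) / scale
    if low is None:
        low = 0.0 if period == 180.0 else -period / 2.0
    out = np.mod(mean - low, period) + low
    if out == low:
        out += period
    return float(out)


def circ_sd(values, period=180.0):
    """Circular standard deviation, in degrees on the given period's scale.

    sqrt(−2 ln R) of the doubled angles, mapped back to the period.  In the
    narrow-dispersion limit this equals the ordinary linear SD.  A single
    value (or any constant list) gives 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 1:
        return 0.0
    z_re, z_im, scale = _resultant(values, period)
    r = min(np.hypot(z_re, z_im), 1.0)
    if r <= 0.0:
        return np.inf
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))) / scale)


def circ_mean_relative(values):
    """Circular mean for relative orientations, returned in (−90, 90]."""
    return circ_mean(values, period=180.0, low=-90.0)
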