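"""Circular statistics on angles in degrees.

Convention used throughout the package: angles are in degrees,
counterclockwise positive, wrapped into [0, 360); absolute circular
differences are reported in [0, 180].
"""

from __future__ import annotations

import numpy as np


def wrap360(angle_deg):
    """Wrap angles into [0, 360)."""
    return np.mod(angle_deg, 360.0)


def circ_diff(a_deg, b_deg):
    """Signed circular difference a - b in (-180, 180]."""
    d = np.mod(np.asarray(a_deg, dtype=float) - b_deg, 360.0)
    return np.where(d > 180.0, d - 360.0, d)


def circ_dist(a_deg, b_deg):
    """Absolute circular difference in [0, 180]."""
    return np.abs(circ_diff(a_deg, b_deg))


def resultant(angles_deg, weights=None):
    """Mean resultant vector of weighted angles.

    Returns (length, mean_angle_deg). Length is in [0, 1]; the mean angle
    is the circular mean, NaN when the total weight or resultant is zero.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
    total = np.nansum(w)
    if total <= 0:
        return 0.0, np.nan
    c = np.nansum(w * np.cos(a)) / total
    s = np.nansum(w * np.sin(a)) / total
    r = float(np.hypot(c, s))
    if r == 0.0:
        return 0.0, np.nan
    mean = float(wrap360(np.rad2deg(np.arctan2(s, c))))
    return r, mean


def circ_mean(angles_deg, weights=None) -> float:
    return resultant(angles_deg, weights)[1]


def mean_vector_length(angles_deg, weights=None) -> float:
    return resultant(angles_deg, weights)[0]


def rayleigh_test(angles_deg):
    """Rayleigh test of circular uniformity.

    Returns (Z, p) with Z = n * R**2 and the standard small-sample
    correction for the p-value (Zar, Biostatistical Analysis).
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    n = a.size
    if n == 0:
        return np.nan, np.nan
    r, _ = resultant(a)
    z = n * r * r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - (n * r) ** 2)) - (1.0 + 2.0 * n))
    return float(z), float(min(max(p, np.finfo(float).tiny), 1.0))
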