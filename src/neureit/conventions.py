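"""Shared geometric conventions.

All cross-sectional modules (forward model, reconstruction, co-registration,
validation) use one angular convention: angles in degrees, measured
*clockwise* from the fiducial direction, which points to 12 o'clock (+y).
The fiducial is the cuff-opening marker; radial coordinates are in µm unless
a function says otherwise.
"""

from __future__ import annotations

import numpy as np

NERVE_DIAMETER_UM = 1400.0
NERVE_RADIUS_UM = NERVE_DIAMETER_UM / 2.0


def theta_from_xy(x, y):
    """Angle (deg, clockwise from +y / 12 o'clock) of point(s) (x, y). Range [0, 360)."""
    return np.mod(np.degrees(np.arctan2(x, y)), 360.0)


def polar_from_xy(x, y):
    """Return (R, theta_deg) with theta clockwise from 12 o'clock."""
    r = np.hypot(x, y)
    return r, theta_from_xy(x, y)


def xy_from_polar(r, theta_deg):
    """Inverse of :func:`polar_from_xy`."""
    th = np.radians(theta_deg)
    return r * np.sin(th), r * np.cos(th)


def wrap_angle_deg(theta):
    """Wrap angle(s) to [0, 360)."""
    return np.mod(theta, 360.0)


def signed_angle_diff_deg(a, b):
    """Smallest signed difference a − b, in (−180, 180]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + 180.0, 360.0) - 180.0
    return np.where(d == -180.0, 180.0, d)
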