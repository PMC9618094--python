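"""Planar angle arithmetic on the arena's horizontal (x, z) plane.

All angles are degrees. The internal convention is a mathematical bearing:
0 deg points along +x (east), angles increase counterclockwise toward +z,
and every angle is wrapped into the half-open interval (-180, +180], with
ties at the boundary resolved to +180.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_deg",
    "bearing",
    "angular_deviation",
    "circular_mean_deg",
    "yaw_to_heading",
    "heading_to_yaw",
]


def wrap_deg(angle):
    """Wrap angle(s) into (-180, +180]; the boundary maps to +180."""
    a = np.asarray(angle, dtype=float)
    # map to [-180, 180) then flip the -180 edge to +180
    w = (a + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    if np.ndim(angle) == 0:
        return float(w)
    return w


def bearing(from_pt, to_pt):
    """Bearing of the vector from_pt -> to_pt, degrees in (-180, +180].

    (0,0)->(1,0) is 0 deg (+x axis); (0,0)->(0,1) is +90 deg (+z axis).
    Accepts Point2D-like objects (with .x/.z) or (x, z) pairs.

    Raises ValueError when the two points coincide (bearing undefined).
    """
    fx, fz = _xz(from_pt)
    tx, tz = _xz(to_pt)
    dx, dz = tx - fx, tz - fz
    if dx == 0.0 and dz == 0.0:
        raise ValueError("bearing undefined: from and to coincide")
    return wrap_deg(np.degrees(np.arctan2(dz, dx)))


def angular_deviation(a, b):
    """Signed wrapped difference a - b in (-180, +180].

    Antisymmetric up to the +180 boundary: deviation(0, 180) == +180 and
    deviation(180, 0) == +180 by the documented tie-break.
    """
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def circular_mean_deg(angles):
    """Circular mean of angles in degrees, wrapped into (-180, +180].

    Uses the direction of the mean unit vector, so the result is stable
    across the +/-180 boundary (unlike an arithmetic mean of wrapped values).
    """
    a = np.radians(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("circular mean of an empty set is undefined")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    if s == 0.0 and c == 0.0:
        raise ValueError("circular mean undefined: resultant vector is zero")
    return wrap_deg(np.degrees(np.arctan2(s, c)))


def yaw_to_heading(yaw):
    """Convert a game yaw (clockwise from +z / 'south') to the math bearing.

    Yaw 0 faces +z (bearing +90); yaw +90 faces -x (bearing 180). Utility for
    adapting raw game-mod logs; the canonical log format already stores math
    bearings.
    """
    return wrap_deg(np.asarray(yaw, dtype=float) + 90.0)


def heading_to_yaw(heading):
    """Inverse of :func:`yaw_to_heading`."""
    return wrap_deg(np.asarray(heading, dtype=float) - 90.0)


def _xz(pt):
    if hasattr(pt, "x") and hasattr(pt, "z"):
        return float(pt.x), float(pt.z)
    x, z = pt
    return float(x), float(z)
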