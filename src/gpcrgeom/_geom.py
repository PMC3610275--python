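"""Low-level vector geometry shared by all analysis modules.

All angles are in degrees.  Dihedrals follow the IUPAC sign convention
(cis = 0, right-handed positive) and are reported in (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "dihedral",
    "angle",
    "distance",
    "place_atom",
    "rotation_about_axis",
    "wrap_angle",
    "circular_mean",
    "circular_sd",
]


class DegenerateGeometryError(ValueError):
    """Raised when coincident or collinear points make an angle undefined."""


_EPS = 1e-10


def wrap_angle(deg):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(deg, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0  # maps -180 -> 180
    return wrapped if wrapped.ndim else float(wrapped)


def distance(p1, p2) -> float:
    return float(np.linalg.norm(np.asarray(p2, float) - np.asarray(p1, float)))


def angle(p1, p2, p3) -> float:
    """Angle at p2 between p1 and p3, in [0, 180] degrees."""
    v1 = np.asarray(p1, float) - np.asarray(p2, float)
    v2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < _EPS or n2 < _EPS:
        raise DegenerateGeometryError("coincident points in angle computation")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral p1-p2-p3-p4 in (-180, 180] degrees (IUPAC, cis = 0)."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < _EPS:
            raise DegenerateGeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError("collinear points make dihedral undefined")
    b2u = b2 / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2u)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float):
    """Place atom D so that |C-D| = bond_length, angle(B,C,D) = bond_angle
    and dihedral(A,B,C,D) = torsion (degrees).  Standard NeRF construction.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise DegenerateGeometryError("collinear reference atoms in placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond_length * np.cos(theta),
            bond_length * np.sin(theta) * np.cos(chi),
            bond_length * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix for a right-handed rotation about *axis*."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    return np.array(
        [
            [c + ux * ux * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy * uy * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz * uz * (1 - c)],
        ]
    )


def circular_mean(deg_values) -> float:
    """Mean direction of angles in degrees, NaN-aware, result in (-180, 180]."""
    a = np.radians(np.asarray(deg_values, float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        return float("nan")
    s, c = np.mean(np.sin(a)), np.mean(np.cos(a))
    return wrap_angle(np.degrees(np.arctan2(s, c)))


def circular_sd(deg_values) -> float:
    """Circular standard deviation sqrt(-2 ln R) in degrees, NaN-aware."""
    a = np.radians(np.asarray(deg_values, float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        return float("nan")
    r = np.hypot(np.mean(np.sin(a)), np.mean(np.cos(a)))
    r = min(max(r, 1e-12), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))
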