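"""Small internal-coordinate and vector geometry helpers."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion a-b-c-d in degrees, IUPAC convention."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d bonded to c with angle(b,c,d) and the
    given torsion about b-c, angles in degrees.

    The torsion argument uses the left-handed screw sense:
    ``dihedral_deg(a, b, c, place_atom(..., torsion=t)) == -t``.  Every
    torsion table in this package follows the same convention, so values
    are interchanged consistently; negate when comparing against
    IUPAC-signed dihedrals from other software.
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def rotation_about_axis(axis: np.ndarray, angle_degrees: float) -> np.ndarray:
    """Rotation matrix about a (normalised) axis through the origin."""
    u = unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_degrees)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    k = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(u, u)


def rotation_aligning(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector src onto unit vector dst."""
    s, d = unit(src), unit(dst)
    v = np.cross(s, d)
    c = float(np.dot(s, d))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any perpendicular axis
        perp = np.cross(s, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(s, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k * (1 / (1 + c))
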