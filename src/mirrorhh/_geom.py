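"""Low-level vector geometry helpers shared across the package.

All angles here are in degrees unless a name says otherwise; positions are
Cartesian, in angstroms.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize",
    "angle_deg",
    "dihedral_deg",
    "wrap180",
    "wrap360",
    "place_by_zmatrix",
    "place_by_two_angles",
    "rotation_about_axis",
]


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def wrap180(angle: np.ndarray | float):
    """Wrap angle(s) to the torsion convention (-180, 180]."""
    a = -np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) + 180.0
    return a


def wrap360(angle: np.ndarray | float):
    """Wrap angle(s) to [0, 360)."""
    return np.mod(np.asarray(angle, dtype=float), 360.0)


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c."""
    u = normalize(np.asarray(a, float) - b)
    v = normalize(np.asarray(c, float) - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral_deg(p1, p2, p3, p4) -> float:
    """Torsion p1-p2-p3-p4 in (-180, 180], IUPAC sign convention.

    Positive means: looking from p2 toward p3, the far bond p3-p4 is rotated
    clockwise relative to the near bond p2-p1.  Uses the atan2 formulation,
    which is stable near +-180.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) == 0 or np.linalg.norm(b2) == 0 or np.linalg.norm(b3) == 0:
        raise ValueError("degenerate geometry: zero-length bond vector in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 to honour the (-180, 180] convention
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def rotation_about_axis(axis: np.ndarray, angle_deg_: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through the origin."""
    k = normalize(np.asarray(axis, float))
    t = np.radians(angle_deg_)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)


def place_by_zmatrix(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d such that |d-c| = bond, angle(d,c,b) = angle and
    dihedral(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = normalize(c - b)
    ba = a - b
    n = normalize(np.cross(ba, bc))
    m = np.cross(n, bc)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            -bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    # basis: bc, m, n; signs chosen so dihedral(a, b, c, d) == torsion
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def place_by_two_angles(center, nb1, nb2, bond: float, angle1: float, angle2: float,
                        branch: float = 1.0) -> np.ndarray:
    """Place atom d bonded to `center` with prescribed angles to two existing
    neighbours nb1 and nb2.

    angle1 = angle(d, center, nb1), angle2 = angle(d, center, nb2).  `branch`
    (+1/-1) selects the side of the nb1-center-nb2 plane; +1 points along
    u x v where u, v are the unit vectors center->nb1, center->nb2.
    """
    center = np.asarray(center, float)
    u = normalize(np.asarray(nb1, float) - center)
    v = normalize(np.asarray(nb2, float) - center)
    w = np.cross(u, v)
    wn = np.linalg.norm(w)
    if wn < 1e-8:
        raise ValueError("two-angle placement needs non-collinear neighbours")
    w = w / wn
    c1 = np.cos(np.radians(angle1))
    c2 = np.cos(np.radians(angle2))
    uv = np.dot(u, v)
    # solve d_hat = alpha*u + beta*v + gamma*w with u.d=c1, v.d=c2
    det = 1.0 - uv * uv
    alpha = (c1 - c2 * uv) / det
    beta = (c2 - c1 * uv) / det
    planar = alpha * u + beta * v
    gamma_sq = 1.0 - float(np.dot(planar, planar))
    gamma = np.sqrt(max(gamma_sq, 0.0)) * (1.0 if branch >= 0 else -1.0)
    d_hat = planar + gamma * w
    return center + bond * normalize(d_hat)
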