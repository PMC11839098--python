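"""Small vector-geometry helpers shared by the chain builder and order parameters."""

from __future__ import annotations

import numpy as np


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (both in degrees)."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    # local displacement in the (bc, m, n) frame
    d2 = bond * np.array([-np.cos(ang),
                          np.sin(ang) * np.cos(tor),
                          -np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees."""
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (for invariance tests)."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(random_state=rng).as_matrix()
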