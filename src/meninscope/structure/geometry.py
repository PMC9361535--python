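"""Elementary 3-D geometry for side-chain construction.

Everything works on plain ``float64`` numpy arrays of shape ``(3,)`` or
``(n, 3)``; angles are in degrees at the public surface (the convention of
rotamer libraries) and radians internally.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dihedral", "bond_angle", "place_atom"]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle a-b-c-d in degrees, in (-180, 180]."""
    b1 = np.asarray(b, float) - np.asarray(a, float)
    b2 = np.asarray(c, float) - np.asarray(b, float)
    b3 = np.asarray(d, float) - np.asarray(c, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c at vertex b, degrees in [0, 180]."""
    v1 = _unit(np.asarray(a, float) - np.asarray(b, float))
    v2 = _unit(np.asarray(c, float) - np.asarray(b, float))
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """Place atom d so that |c-d| = bond_length, angle(b,c,d) = angle_deg and
    dihedral(a,b,c,d) = torsion_deg (natural-extension / NeRF construction)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.radians(angle_deg)
    chi = -np.radians(torsion_deg)  # frame below is left-handed in the torsion

    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)

    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
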