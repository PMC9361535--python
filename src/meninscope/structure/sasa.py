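"""Per-residue solvent accessibility.

Shrake–Rupley sphere-point SASA computed directly on the structure's
coordinate arrays, then normalized per residue by the theoretical maximum
accessibility of that residue type in an extended Gly-X-Gly tripeptide
(Tien et al. 2013, "theoretical" column).  The sphere-point count is a
parameter so the estimate can be refined for verification.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np
from scipy.spatial import cKDTree

from .model import ResidueKey, StructureModel

__all__ = ["VDW_RADII", "MAX_SASA_GXG", "shrake_rupley_sasa", "relative_sasa"]

# heavy-atom van der Waals radii, Å
VDW_RADII: Dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
_DEFAULT_RADIUS = 1.80

# theoretical maximum SASA (Å^2) in extended Gly-X-Gly, Tien et al. 2013
MAX_SASA_GXG: Dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley_sasa(
    model: StructureModel, probe_radius: float = 1.4, n_points: int = 196
) -> np.ndarray:
    """Per-atom SASA in Å²; deterministic for a fixed ``n_points``."""
    if model.n_atoms == 0:
        raise ValueError("empty structure")
    radii = np.array(
        [VDW_RADII.get(el, _DEFAULT_RADIUS) for el in model.elements], float
    ) + probe_radius
    coords = model.coords
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(model.n_atoms)
    for i in range(model.n_atoms):
        pts = coords[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        if neigh:
            d2 = ((pts[:, None, :] - coords[neigh][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[neigh] ** 2)[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_points
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * exposed / n_points
    return areas


def relative_sasa(
    model: StructureModel, probe_radius: float = 1.4, n_points: int = 196
) -> Dict[ResidueKey, float]:
    """Relative accessibility per residue, capped at 1.2.

    Unknown residue types get ``nan`` (flagged missing, never zero).
    """
    atom_sasa = shrake_rupley_sasa(model, probe_radius, n_points)
    out: Dict[ResidueKey, float] = {}
    for key, ids in model.residue_index.items():
        ref = MAX_SASA_GXG.get(model.residue_name(key))
        if ref is None:
            out[key] = float("nan")
        else:
            out[key] = min(float(atom_sasa[ids].sum()) / ref, 1.2)
    return out
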