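"""Steric clash counting for candidate rotamers.

A rotamer clashes when any of its side-chain heavy atoms comes closer than
``vdW_i + vdW_j − tolerance`` to any atom of another residue.  The mutated
residue's own atoms are excluded, as are the bonded-neighbour backbone atoms
(C/O of the preceding and N of the following residue) whose 1-3/1-4
covalent geometry would otherwise register as contact for every CB.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .model import ResidueKey, StructureModel
from .rotamers import SidechainPlacement
from .sasa import VDW_RADII, _DEFAULT_RADIUS

__all__ = ["StabilityClass", "clash_fraction", "rotamer_clashes"]

#: stability call from the fraction of clashing rotamers
StabilityClass = str  # "stable" | "potentially_stable" | "unstable"


def _environment_indices(model: StructureModel, position: ResidueKey) -> np.ndarray:
    """Atom indices the rotamer is tested against."""
    chain, num, icode = position
    excluded_atoms = set(model.residue_index[position])
    for other_key in ((chain, num - 1, ""), (chain, num - 1, icode)):
        if other_key in model.residue_index:
            for name in ("C", "O"):
                i = model.atom_index(other_key, name)
                if i is not None:
                    excluded_atoms.add(i)
    for other_key in ((chain, num + 1, ""), (chain, num + 1, icode)):
        if other_key in model.residue_index:
            i = model.atom_index(other_key, "N")
            if i is not None:
                excluded_atoms.add(i)
    return np.array(
        [i for i in range(model.n_atoms) if i not in excluded_atoms], dtype=int
    )


def rotamer_clashes(
    placements: Sequence[SidechainPlacement],
    model: StructureModel,
    overlap_tolerance: float = 0.4,
) -> List[bool]:
    """Per-rotamer clash verdicts against the rest of the structure."""
    if not placements:
        raise ValueError("no placements given")
    if overlap_tolerance < 0:
        raise ValueError("tolerance must be ≥ 0")
    position = placements[0].residue_key
    env = _environment_indices(model, position)
    if env.size == 0:
        return [False] * len(placements)
    env_coords = model.coords[env]
    env_radii = np.array(
        [VDW_RADII.get(model.elements[i], _DEFAULT_RADIUS) for i in env], float
    )
    tree = cKDTree(env_coords)
    max_env_r = float(env_radii.max())

    verdicts: List[bool] = []
    for pl in placements:
        clash = False
        for k in range(pl.coords.shape[0]):
            r_self = VDW_RADII.get(pl.elements[k], _DEFAULT_RADIUS)
            cutoff = r_self + max_env_r - overlap_tolerance
            for j in tree.query_ball_point(pl.coords[k], cutoff):
                d = float(np.linalg.norm(pl.coords[k] - env_coords[j]))
                if d < r_self + env_radii[j] - overlap_tolerance:
                    clash = True
                    break
            if clash:
                break
        verdicts.append(clash)
    return verdicts


def clash_fraction(
    placements: Sequence[SidechainPlacement],
    model: StructureModel,
    overlap_tolerance: float = 0.4,
) -> Tuple[float, StabilityClass]:
    """Fraction of clashing rotamers and the stability call.

    0 → ``stable``; 1 → ``unstable``; anything between → ``potentially_stable``.
    Placements with no side-chain atoms (Gly) cannot clash by construction.
    """
    verdicts = rotamer_clashes(placements, model, overlap_tolerance)
    frac = float(np.mean(verdicts))
    if frac == 0.0:
        return 0.0, "stable"
    if frac == 1.0:
        return 1.0, "unstable"
    return frac, "potentially_stable"
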