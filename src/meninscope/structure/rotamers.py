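"""Side-chain rotamer enumeration on a fixed backbone.

For a candidate mutant residue type, side chains are rebuilt atom by atom
from ideal internal coordinates (bond lengths, angles and torsion offsets
measured once from the Chemical Component Dictionary templates bundled with
:mod:`biotite`) anchored on the existing backbone N/CA/C, with the rotatable
χ torsions substituted from a rotamer library.

The default library is combinatorial over per-bond candidate angles
(sp3 bonds at the three staggered positions, terminal sp2 groups at a small
per-chemistry set) rather than a survey-derived library; it is pluggable —
any mapping from residue type to χ-tuples with the same shape works.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import biotite.structure as bst
import biotite.structure.info as bstinfo

from .geometry import dihedral, place_atom
from .model import ResidueKey, StructureModel

__all__ = [
    "AA3_TO_1", "AA1_TO_3", "RotamerLibrary", "SidechainPlacement",
    "default_rotamer_library", "enumerate_rotamers", "CHI_ATOMS",
]

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# canonical χ-defining atom quadruples per residue type
CHI_ATOMS: Dict[str, List[Tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [],  # ring-constrained; built at template geometry
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

_SP3 = (-60.0, 60.0, 180.0)
# terminal planar groups: symmetric (carboxylate / aromatic ring) vs asymmetric (amide / imidazole / indole)
_SP2_SYM = (0.0, 90.0)
_SP2_ASYM = (-90.0, 0.0, 90.0)

_CHI_CANDIDATES: Dict[str, List[Tuple[float, ...]]] = {
    "ARG": [_SP3, _SP3, _SP3, (-90.0, 90.0, 180.0)],
    "ASN": [_SP3, _SP2_ASYM],
    "ASP": [_SP3, _SP2_SYM],
    "CYS": [_SP3],
    "GLN": [_SP3, _SP3, _SP2_ASYM],
    "GLU": [_SP3, _SP3, _SP2_SYM],
    "HIS": [_SP3, _SP2_ASYM],
    "ILE": [_SP3, _SP3],
    "LEU": [_SP3, _SP3],
    "LYS": [_SP3, _SP3, _SP3, _SP3],
    "MET": [_SP3, _SP3, _SP3],
    "PHE": [_SP3, _SP2_SYM],
    "PRO": [],
    "SER": [_SP3],
    "THR": [_SP3],
    "TRP": [_SP3, _SP2_ASYM],
    "TYR": [_SP3, _SP2_SYM],
    "VAL": [_SP3],
}

#: maps 1-letter residue type to a list of χ-angle tuples (degrees)
RotamerLibrary = Dict[str, List[Tuple[float, ...]]]


def default_rotamer_library() -> RotamerLibrary:
    """Combinatorial ideal-geometry rotamer library.

    Gly and Ala map to an empty list (no χ angles); Pro maps to a single
    template-geometry conformer.
    """
    lib: RotamerLibrary = {"G": [], "A": []}
    for res3, cands in _CHI_CANDIDATES.items():
        aa1 = AA3_TO_1[res3]
        if not cands:
            lib[aa1] = [()]
            continue
        lib[aa1] = [tuple(combo) for combo in itertools.product(*cands)]
    return lib


# ---------------------------------------------------------------------------
# internal-coordinate templates from CCD ideal residues
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _AtomIC:
    name: str
    element: str
    frame: Tuple[str, str, str]      # a, b, c — torsion is a-b-c-self
    length: float
    angle: float
    torsion: float                   # template value, degrees
    chi_index: Optional[int]         # 0-based χ the (b,c) bond corresponds to
    chi_offset: float                # self torsion − canonical χ torsion


@dataclass(frozen=True)
class _SidechainTemplate:
    res3: str
    atoms: Tuple[_AtomIC, ...]       # in buildable order


@lru_cache(maxsize=None)
def _sidechain_template(res3: str) -> _SidechainTemplate:
    res = bstinfo.residue(res3)
    heavy = res[(res.element != "H") & (res.atom_name != "OXT")]
    names = list(heavy.atom_name)
    coord = {n: heavy.coord[i] for i, n in enumerate(names)}
    bonds: Dict[str, set] = {n: set() for n in names}
    idx = {n: i for i, n in enumerate(names)}
    all_bonds, _ = heavy.bonds.get_all_bonds()
    for i, n in enumerate(names):
        for j in all_bonds[i]:
            if j >= 0 and heavy.atom_name[j] in idx:
                bonds[n].add(heavy.atom_name[j])

    # virtual parent chain C -> N -> CA seeds the NeRF frames
    parent: Dict[str, str] = {"CA": "N", "N": "C"}
    order: List[str] = []
    frontier = ["CA"]
    seen = {"N", "CA", "C", "O"}
    while frontier:
        cur = frontier.pop(0)
        for nb in sorted(bonds[cur]):
            if nb in seen or nb in parent:
                continue
            parent[nb] = cur
            seen.add(nb)
            order.append(nb)
            frontier.append(nb)

    chi_quads = CHI_ATOMS.get(res3, [])
    chi_bonds = {(q[1], q[2]): k for k, q in enumerate(chi_quads)}
    chi_template = {
        k: dihedral(coord[q[0]], coord[q[1]], coord[q[2]], coord[q[3]])
        for k, q in enumerate(chi_quads)
    }

    atoms: List[_AtomIC] = []
    for name in order:
        c = parent[name]
        b = parent[c]
        a = parent[b]
        tors = dihedral(coord[a], coord[b], coord[c], coord[name])
        ci = chi_bonds.get((b, c))
        off = tors - chi_template[ci] if ci is not None else 0.0
        atoms.append(
            _AtomIC(
                name=name,
                element=str(heavy.element[idx[name]]),
                frame=(a, b, c),
                length=float(np.linalg.norm(coord[name] - coord[c])),
                angle=_angle(coord[b], coord[c], coord[name]),
                torsion=tors,
                chi_index=ci,
                chi_offset=off,
            )
        )
    return _SidechainTemplate(res3=res3, atoms=tuple(atoms))


def _angle(b, c, d) -> float:
    v1 = b - c
    v2 = d - c
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# placements
# ---------------------------------------------------------------------------

@dataclass
class SidechainPlacement:
    """One candidate side-chain conformation on the fixed backbone."""
    residue_key: ResidueKey
    mutant_aa: str
    atom_names: List[str]
    elements: List[str]
    coords: np.ndarray               # (n_sidechain_atoms, 3)
    chis: Tuple[float, ...]


def build_sidechain(
    n: np.ndarray, ca: np.ndarray, c: np.ndarray, res3: str,
    chis: Sequence[float],
) -> Tuple[List[str], List[str], np.ndarray]:
    """Build side-chain heavy atoms (CB onward) for ``res3`` on the given
    backbone with the given χ angles; returns (names, elements, coords)."""
    tmpl = _sidechain_template(res3)
    pos: Dict[str, np.ndarray] = {"N": np.asarray(n, float),
                                  "CA": np.asarray(ca, float),
                                  "C": np.asarray(c, float)}
    names: List[str] = []
    elements: List[str] = []
    for atom in tmpl.atoms:
        if atom.chi_index is not None:
            if atom.chi_index >= len(chis):
                raise ValueError(
                    f"{res3} needs {atom.chi_index + 1} χ angles, got {len(chis)}"
                )
            tors = chis[atom.chi_index] + atom.chi_offset
        else:
            tors = atom.torsion
        a, b, cc = (pos[x] for x in atom.frame)
        pos[atom.name] = place_atom(a, b, cc, atom.length, atom.angle, tors)
        names.append(atom.name)
        elements.append(atom.element)
    coords = np.array([pos[nm] for nm in names], float).reshape(-1, 3)
    return names, elements, coords


def enumerate_rotamers(
    model: StructureModel,
    position: ResidueKey,
    mutant_aa: str,
    library: Optional[RotamerLibrary] = None,
) -> List[SidechainPlacement]:
    """All candidate side-chain placements for mutating ``position`` to
    ``mutant_aa``.

    Gly returns a single placement with no side-chain atoms; Ala a single
    placement holding only CB.  Raises ``KeyError`` if the position is not in
    the model and ``ValueError`` naming the atom if backbone atoms are absent.
    """
    if library is None:
        library = default_rotamer_library()
    if position not in model.residue_index:
        raise KeyError(f"residue {position} not resolved in structure")
    if mutant_aa not in AA1_TO_3:
        raise ValueError(f"unknown amino acid {mutant_aa!r}")
    backbone = {}
    for atom in ("N", "CA", "C"):
        i = model.atom_index(position, atom)
        if i is None:
            raise ValueError(f"missing backbone atom {atom} at {position}")
        backbone[atom] = model.coords[i]

    if mutant_aa == "G":
        return [SidechainPlacement(position, "G", [], [],
                                   np.empty((0, 3)), ())]

    res3 = AA1_TO_3[mutant_aa]
    chi_sets: List[Tuple[float, ...]]
    if mutant_aa == "A":
        chi_sets = [()]
    else:
        chi_sets = library.get(mutant_aa) or [()]

    placements = []
    for chis in chi_sets:
        names, elements, coords = build_sidechain(
            backbone["N"], backbone["CA"], backbone["C"], res3, chis
        )
        placements.append(
            SidechainPlacement(position, mutant_aa, names, elements, coords,
                               tuple(chis))
        )
    return placements
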