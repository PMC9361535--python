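"""Toy protein structures with planted, known geometry.

The generator builds a single chain with ideal backbone geometry (NeRF
construction at fixed φ/ψ/ω) and full template side chains, then plants
verifiable features:

* **clash sites** — a blocker carbon fixed within van-der-Waals overlap of
  the CB position of a residue, so *every* rotamer of any non-Gly mutant
  type at that position clashes;
* **H-bond pairs** — the site residue becomes Ser and a free-floating Asp
  is oriented so its OD1 sits at a configurable donor–acceptor distance
  (default 2.8 Å) from the Ser OG;
* **interface contacts** — a partner chain of alanines placed so one CB
  lies ~4 Å from the CA of each designated residue, inside the 5-Å contact
  zone.

Ground truth records exactly what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..structure.geometry import place_atom
from ..structure.model import StructureModel
from ..structure.rotamers import AA1_TO_3, build_sidechain, _sidechain_template
import biotite.structure.info as bstinfo

__all__ = ["StructureSpec", "StructureGroundTruth", "make_toy_structure", "build_backbone"]

# ideal backbone internal coordinates (Å, degrees)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.2, 121.7, 120.8


@dataclass
class StructureSpec:
    n_residues: int = 12
    sequence: Optional[str] = None           # 1-letter; default poly-Leu
    phi: float = -120.0
    psi: float = 130.0
    clash_positions: Tuple[int, ...] = ()    # 1-based residue numbers
    hbond_positions: Tuple[int, ...] = ()    # residue becomes Ser + Asp partner
    hbond_distance: float = 2.8
    interface_positions: Tuple[int, ...] = ()
    chain_id: str = "A"
    partner_chain_id: str = "B"


@dataclass
class StructureGroundTruth:
    clash_positions: Tuple[int, ...]
    hbond_positions: Tuple[int, ...]
    interface_positions: Tuple[int, ...]
    sequence: str
    chain_id: str
    partner_chain_id: str


def build_backbone(
    n_residues: int, phi: float, psi: float, omega: float = 180.0
) -> List[Dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for an ideal-geometry chain."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    res: List[Dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_N_CA, 0.0, 0.0])
    c0 = place_atom(
        np.array([0.0, 1.0, 0.0]), n0, ca0, _CA_C, _ANG_N_CA_C, 55.0
    )
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_residues):
        prev = res[-1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"], _C_N, _ANG_CA_C_N, psi)
        ca_i = place_atom(prev["CA"], prev["C"], n_i, _N_CA, _ANG_C_N_CA, omega)
        c_i = place_atom(prev["C"], n_i, ca_i, _CA_C, _ANG_N_CA_C, phi)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: trans to the next amide nitrogen (or ψ+180 at the end)
    for i, r in enumerate(res):
        if i + 1 < len(res):
            r["O"] = place_atom(res[i + 1]["N"], r["CA"], r["C"], _C_O, _ANG_CA_C_O, 180.0)
        else:
            r["O"] = place_atom(r["N"], r["CA"], r["C"], _C_O, _ANG_CA_C_O, 0.0)
    return res


def _default_chis(res3: str) -> Tuple[float, ...]:
    from ..structure.rotamers import CHI_ATOMS

    n_chi = len(CHI_ATOMS.get(res3, []))
    return tuple([-60.0] * n_chi)


def _isolated_residue(res3: str) -> Tuple[List[str], List[str], np.ndarray]:
    """Heavy atoms of one template residue (names, elements, coords)."""
    res = bstinfo.residue(res3)
    h = res[(res.element != "H") & (res.atom_name != "OXT")]
    return list(h.atom_name), list(h.element), np.asarray(h.coord, float)


def _rotation_between(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    a = v_from / np.linalg.norm(v_from)
    b = v_to / np.linalg.norm(v_to)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def make_toy_structure(
    spec: StructureSpec, seed: int = 0
) -> Tuple[str, StructureGroundTruth]:
    """Emit PDB text plus ground truth for the planted features."""
    rng = np.random.default_rng(seed)
    n = spec.n_residues
    seq = spec.sequence or "L" * n
    if len(seq) != n:
        raise ValueError("sequence length does not match n_residues")
    seq = list(seq)
    for p in spec.hbond_positions:
        if p in spec.clash_positions:
            raise ValueError(f"position {p} cannot be both clash and H-bond plant")
        seq[p - 1] = "S"

    backbone = build_backbone(n, spec.phi, spec.psi)
    names: List[str] = []
    elements: List[str] = []
    res_names: List[str] = []
    chains: List[str] = []
    keys: List[Tuple[str, int, str]] = []
    coords: List[np.ndarray] = []

    def emit(atom: str, element: str, res3: str, chain: str, num: int, xyz) -> None:
        names.append(atom)
        elements.append(element)
        res_names.append(res3)
        chains.append(chain)
        keys.append((chain, num, ""))
        coords.append(np.asarray(xyz, float))

    for i, r in enumerate(backbone):
        num = i + 1
        res3 = AA1_TO_3[seq[i]]
        for atom in ("N", "CA", "C", "O"):
            emit(atom, atom[0], res3, spec.chain_id, num, r[atom])
        if seq[i] != "G":
            sc_names, sc_els, sc_xyz = build_sidechain(
                r["N"], r["CA"], r["C"], res3, _default_chis(res3)
            )
            for nm, el, xyz in zip(sc_names, sc_els, sc_xyz):
                emit(nm, el, res3, spec.chain_id, num, xyz)

    centroid = np.mean([r["CA"] for r in backbone], axis=0)

    def outward(num: int) -> np.ndarray:
        ca = backbone[num - 1]["CA"]
        d = ca - centroid
        d = d + np.array([0.0, 0.0, 1e-3])
        return d / np.linalg.norm(d)

    # clash blockers: one carbon sitting on each planted CB position
    blocker_num = 900
    for p in spec.clash_positions:
        r = backbone[p - 1]
        sc_names, _, sc_xyz = build_sidechain(r["N"], r["CA"], r["C"], "ALA", ())
        cb = sc_xyz[sc_names.index("CB")]
        emit("CA", "C", "ALA", "Z", blocker_num, cb + 0.3 * outward(p))
        blocker_num += 1

    # H-bond partners: floating Asp with OD1 near the planted Ser OG.
    # χ1 is chosen so OG stays clear of the chain's own polar atoms and the
    # planted bond is the only polar contact at the site.
    chain_polar = np.array(
        [c for c, nm, ch in zip(coords, names, chains)
         if ch == spec.chain_id and nm in ("N", "O")]
    )
    partner_num = 500
    for p in spec.hbond_positions:
        r = backbone[p - 1]
        best = None
        for chi1 in (-60.0, 60.0, 180.0):
            sc_names, _, sc_xyz = build_sidechain(r["N"], r["CA"], r["C"], "SER", (chi1,))
            og_try = sc_xyz[sc_names.index("OG")]
            clearance = np.min(np.linalg.norm(chain_polar - og_try, axis=1))
            if best is None or clearance > best[0]:
                best = (clearance, chi1, sc_names, sc_xyz)
        _, chi1, sc_names, sc_xyz = best
        # rebuild the emitted Ser side chain with the chosen χ1
        for k in range(len(names)):
            if keys[k] == (spec.chain_id, p, "") and names[k] in ("CB", "OG"):
                coords[k] = sc_xyz[sc_names.index(names[k])]
        og = sc_xyz[sc_names.index("OG")]
        a_names, a_els, a_xyz = _isolated_residue("ASP")
        od1 = a_xyz[a_names.index("OD1")]
        body = a_xyz.mean(axis=0) - od1
        rot = _rotation_between(body, outward(p))
        a_xyz = (a_xyz - od1) @ rot.T + og + spec.hbond_distance * outward(p)
        for nm, el, xyz in zip(a_names, a_els, a_xyz):
            emit(nm, el, "ASP", "D", partner_num, xyz)
        partner_num += 1

    # interface partner chain: alanines with CB ~4 Å from target CA
    for j, p in enumerate(spec.interface_positions):
        r = backbone[p - 1]
        a_names, a_els, a_xyz = _isolated_residue("ALA")
        cb = a_xyz[a_names.index("CB")]
        body = a_xyz.mean(axis=0) - cb
        rot = _rotation_between(body, outward(p))
        a_xyz = (a_xyz - cb) @ rot.T + r["CA"] + 4.0 * outward(p)
        for nm, el, xyz in zip(a_names, a_els, a_xyz):
            emit(nm, el, "ALA", spec.partner_chain_id, j + 1, xyz)

    model = StructureModel(
        source_id="synthetic",
        atom_names=names,
        elements=elements,
        res_names=res_names,
        chains=chains,
        res_keys=keys,
        coords=np.array(coords),
        occupancies=np.ones(len(names)),
        altlocs=[""] * len(names),
    )
    truth = StructureGroundTruth(
        clash_positions=tuple(spec.clash_positions),
        hbond_positions=tuple(spec.hbond_positions),
        interface_positions=tuple(spec.interface_positions),
        sequence="".join(seq),
        chain_id=spec.chain_id,
        partner_chain_id=spec.partner_chain_id,
    )
    return model.to_pdb(), truth
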