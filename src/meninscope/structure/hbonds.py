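"""Side-chain hydrogen bonds and salt bridges by distance criteria.

Typing is purely chemical (which atoms of which residue type can donate,
accept, or carry charge); the geometric criterion is heavy-atom distance
only — donor–acceptor ≤ 3.5 Å for hydrogen bonds, opposite-charge group
atoms ≤ 4.0 Å for salt bridges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Set

import numpy as np
from scipy.spatial import cKDTree

from .model import ResidueKey, StructureModel

__all__ = [
    "PolarContact", "hydrogen_bonds", "sidechain_capabilities",
    "SIDECHAIN_DONORS", "SIDECHAIN_ACCEPTORS", "POSITIVE_ATOMS", "NEGATIVE_ATOMS",
]

SIDECHAIN_DONORS: Dict[str, Set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "TRP": {"NE1"},
}
SIDECHAIN_ACCEPTORS: Dict[str, Set[str]] = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "ASN": {"OD1"}, "GLN": {"OE1"},
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
POSITIVE_ATOMS: Dict[str, Set[str]] = {
    "LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}
NEGATIVE_ATOMS: Dict[str, Set[str]] = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"},
}


@dataclass(frozen=True)
class PolarContact:
    kind: str                 # "hbond" | "salt_bridge"
    self_atom: str
    self_role: str            # "donor" | "acceptor" | "positive" | "negative"
    partner: ResidueKey
    partner_atom: str
    distance: float


def sidechain_capabilities(res3: str) -> Dict[str, bool]:
    """Which polar roles a residue type's side chain can play."""
    return {
        "donor": res3 in SIDECHAIN_DONORS,
        "acceptor": res3 in SIDECHAIN_ACCEPTORS,
        "positive": res3 in POSITIVE_ATOMS,
        "negative": res3 in NEGATIVE_ATOMS,
    }


def hydrogen_bonds(
    model: StructureModel,
    position: ResidueKey,
    hbond_cutoff: float = 3.5,
    salt_cutoff: float = 4.0,
) -> List[PolarContact]:
    """All side-chain H-bonds and salt bridges the residue at ``position``
    makes with other residues (side-chain or backbone partners).

    An empty list is a valid result (e.g. glycine).
    """
    res3 = model.residue_name(position)
    own = model.residue_index[position]
    own_set = set(own)

    donors = SIDECHAIN_DONORS.get(res3, set())
    acceptors = SIDECHAIN_ACCEPTORS.get(res3, set())
    positives = POSITIVE_ATOMS.get(res3, set())
    negatives = NEGATIVE_ATOMS.get(res3, set())
    if not (donors or acceptors or positives or negatives):
        return []

    tree = cKDTree(model.coords)
    max_cut = max(hbond_cutoff, salt_cutoff)
    contacts: List[PolarContact] = []
    seen = set()

    for i in own:
        name = model.atom_names[i]
        roles = []
        if name in donors:
            roles.append("donor")
        if name in acceptors:
            roles.append("acceptor")
        if not roles and name not in positives and name not in negatives:
            continue
        for j in tree.query_ball_point(model.coords[i], max_cut):
            if j in own_set:
                continue
            d = float(np.linalg.norm(model.coords[i] - model.coords[j]))
            pres3 = model.res_names[j]
            pname = model.atom_names[j]
            pkey = model.res_keys[j]
            # backbone atoms of the bonded neighbours are near-covalent
            # (1-4/1-5) — never a hydrogen bond
            if (
                pkey[0] == position[0]
                and abs(pkey[1] - position[1]) == 1
                and pname in ("N", "O", "C", "CA")
            ):
                continue
            p_donor = pname in SIDECHAIN_DONORS.get(pres3, set()) or pname == "N"
            p_acceptor = pname in SIDECHAIN_ACCEPTORS.get(pres3, set()) or pname == "O"
            # hydrogen bond
            if d <= hbond_cutoff:
                for role in roles:
                    if (role == "donor" and p_acceptor) or (role == "acceptor" and p_donor):
                        tag = ("hbond", name, pkey, pname)
                        if tag not in seen:
                            seen.add(tag)
                            contacts.append(
                                PolarContact("hbond", name, role, pkey, pname, d)
                            )
            # salt bridge
            if d <= salt_cutoff:
                p_pos = pname in POSITIVE_ATOMS.get(pres3, set())
                p_neg = pname in NEGATIVE_ATOMS.get(pres3, set())
                if name in positives and p_neg:
                    sb = ("salt_bridge", name, pkey, pname)
                    if sb not in seen:
                        seen.add(sb)
                        contacts.append(
                            PolarContact("salt_bridge", name, "positive", pkey, pname, d)
                        )
                elif name in negatives and p_pos:
                    sb = ("salt_bridge", name, pkey, pname)
                    if sb not in seen:
                        seen.add(sb)
                        contacts.append(
                            PolarContact("salt_bridge", name, "negative", pkey, pname, d)
                        )
    contacts.sort(key=lambda c: (c.kind, c.partner, c.distance))
    return contacts
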