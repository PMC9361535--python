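"""Protein–protein interface zones in complex structures.

A menin residue belongs to an interface when any of its atoms lies within
the contact radius (default 5 Å) of any atom of the partner chain — the
MLL1 peptide, LEDGF, or the JunD peptide, depending on the complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .model import ResidueKey, StructureModel

__all__ = ["InterfaceDefinition", "interface_residues"]


@dataclass(frozen=True)
class InterfaceDefinition:
    name: str                       # e.g. "mll1", "mll1_ledgf", "jund"
    complex_id: str                 # e.g. "3U85"
    menin_chains: Tuple[str, ...]
    partner_chains: Tuple[str, ...]
    radius: float = 5.0


def interface_residues(
    complex_model: StructureModel, interface: InterfaceDefinition
) -> Set[ResidueKey]:
    """Menin residues with ≥1 atom within ``interface.radius`` of any
    partner-chain atom."""
    menin_idx = complex_model.chain_atom_indices(interface.menin_chains)
    partner_idx = complex_model.chain_atom_indices(interface.partner_chains)
    if menin_idx.size == 0:
        raise ValueError(f"menin selector {interface.menin_chains} matches no atoms")
    if partner_idx.size == 0:
        raise ValueError(f"partner selector {interface.partner_chains} matches no atoms")
    if interface.radius < 0:
        raise ValueError("radius must be ≥ 0")

    tree = cKDTree(complex_model.coords[partner_idx])
    dists, _ = tree.query(complex_model.coords[menin_idx], k=1)
    hits: Set[ResidueKey] = set()
    for local_i, d in enumerate(dists):
        if d <= interface.radius:
            hits.add(complex_model.res_keys[int(menin_idx[local_i])])
    return hits
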