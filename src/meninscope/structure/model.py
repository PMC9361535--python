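"""In-memory protein structure and PDB input.

:class:`StructureModel` is a flat, array-backed view of one model of a PDB
entry: parallel per-atom arrays plus an ordered residue index keyed by
``(chain, resseq, icode)``.  Parsing is delegated to :mod:`Bio.PDB`; waters
and non-protein heteroatoms are dropped and a single alternate location
(highest occupancy, ties broken toward the lexicographically first altloc,
which is the parser's selection order) is retained per atom.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

__all__ = ["ResidueKey", "StructureModel", "PDBError", "read_structure"]

#: (chain id, residue number, insertion code)
ResidueKey = tuple[str, int, str]


class PDBError(ValueError):
    """Raised for malformed or empty PDB input."""


@dataclass
class StructureModel:
    source_id: str
    atom_names: list[str]
    elements: list[str]
    res_names: list[str]
    chains: list[str]
    res_keys: list[ResidueKey]          # per atom
    coords: np.ndarray                  # (n_atoms, 3) float64, Å
    occupancies: np.ndarray
    altlocs: list[str]
    residue_index: dict[ResidueKey, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise PDBError("non-finite coordinates")
        if not self.residue_index:
            idx: dict[ResidueKey, list[int]] = {}
            for i, key in enumerate(self.res_keys):
                idx.setdefault(key, []).append(i)
            self.residue_index = idx
        for key, ids in self.residue_index.items():
            names = {self.res_names[i] for i in ids}
            if len(names) != 1:
                raise PDBError(f"residue {key} has inconsistent residue types {names}")

    # -- residue-level accessors -------------------------------------------------
    def residues(self) -> list[ResidueKey]:
        return list(self.residue_index)

    def residue_name(self, key: ResidueKey) -> str:
        return self.res_names[self.residue_index[key][0]]

    def residue_atom_indices(self, key: ResidueKey) -> list[int]:
        return self.residue_index[key]

    def atom_index(self, key: ResidueKey, atom_name: str) -> Optional[int]:
        for i in self.residue_index.get(key, []):
            if self.atom_names[i] == atom_name:
                return i
        return None

    def atom_coord(self, key: ResidueKey, atom_name: str) -> np.ndarray:
        i = self.atom_index(key, atom_name)
        if i is None:
            raise KeyError(f"atom {atom_name} not present in residue {key}")
        return self.coords[i]

    def chain_atom_indices(self, chains: Iterable[str]) -> np.ndarray:
        wanted = set(chains)
        return np.array([i for i, c in enumerate(self.chains) if c in wanted], dtype=int)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    # -- output ------------------------------------------------------------------
    def to_pdb(self) -> str:
        """Serialize as minimal single-model PDB text (round-trip stable)."""
        lines = []
        for i in range(self.n_atoms):
            ch, num, icode = self.res_keys[i]
            name = self.atom_names[i]
            # PDB column rule: 4-char names start in col 13, shorter in col 14
            fname = name if len(name) == 4 else f" {name:<3s}"
            x, y, z = self.coords[i]
            lines.append(
                f"ATOM  {i + 1:>5d} {fname}{'':1s}{self.res_names[i]:>3s} "
                f"{ch:1s}{num:>4d}{icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{self.occupancies[i]:6.2f}{0.0:6.2f}"
                f"          {self.elements[i]:>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


_WATER = {"HOH", "WAT", "DOD"}


def _validate_coordinate_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise PDBError(f"malformed coordinate line {lineno}: {line!r}") from None


def read_structure(
    pdb_text: str,
    model_index: int = 0,
    chain_filter: Optional[Iterable[str]] = None,
    source_id: str = "",
) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Waters and non-protein heteroatoms (``HETATM`` with a hetero flag) are
    excluded; one altloc per atom is kept.  ``chain_filter`` restricts to the
    given chain ids and raises if nothing survives.
    """
    _validate_coordinate_lines(pdb_text)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure(source_id or "model", io.StringIO(pdb_text))
    models = list(structure)
    if not models:
        raise PDBError("no atoms")
    try:
        model = models[model_index]
    except IndexError:
        raise PDBError(f"model index {model_index} out of range (have {len(models)})") from None

    wanted = set(chain_filter) if chain_filter is not None else None

    atom_names: list[str] = []
    elements: list[str] = []
    res_names: list[str] = []
    chains: list[str] = []
    res_keys: list[ResidueKey] = []
    coords: list[np.ndarray] = []
    occ: list[float] = []
    altlocs: list[str] = []

    for chain in model:
        if wanted is not None and chain.id not in wanted:
            continue
        for residue in chain:
            hetfield, resseq, icode = residue.id
            if hetfield.strip() or residue.resname.strip() in _WATER:
                continue  # water / ligand / ion
            key: ResidueKey = (chain.id, int(resseq), icode.strip())
            for atom in residue:
                if isinstance(atom, DisorderedAtom):
                    atom = atom.selected_child  # highest occupancy per parser
                if atom.element == "H" or atom.get_name().startswith("H"):
                    continue
                atom_names.append(atom.get_name())
                elements.append(atom.element or atom.get_name()[0])
                res_names.append(residue.resname.strip())
                chains.append(chain.id)
                res_keys.append(key)
                coords.append(np.asarray(atom.coord, float))
                occ.append(float(atom.get_occupancy() or 1.0))
                altlocs.append(atom.get_altloc().strip())

    if not atom_names:
        if wanted is not None:
            raise PDBError(f"no atoms in chains {sorted(wanted)}")
        raise PDBError("no atoms")

    return StructureModel(
        source_id=source_id,
        atom_names=atom_names,
        elements=elements,
        res_names=res_names,
        chains=chains,
        res_keys=res_keys,
        coords=np.array(coords, float),
        occupancies=np.array(occ, float),
        altlocs=altlocs,
    )
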