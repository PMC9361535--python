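"""Structure-based triage of missense mutations.

Each mutation is assessed on the wild-type structure for three kinds of
predicted effect, in decreasing precedence:

1. instability by the rotamer criterion — every candidate side-chain
   conformation of the mutant type clashes sterically with the folded
   structure;
2. loss of side-chain hydrogen bonds or salt bridges the wild-type residue
   makes and the mutant chemistry cannot reproduce;
3. alteration of a protein–protein interface — the position lies within the
   contact radius of a binding partner in a complex structure, is surface
   accessible, and the mutation changes the side chain's polar/charge
   capabilities (loss → predicted disruption, addition → possible gain).

Positions not resolved in the monomer cannot be assessed and are reported
as ``pathogenic_unknown``.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .structure.clashes import clash_fraction as _clash_fraction
from .structure.hbonds import hydrogen_bonds, sidechain_capabilities
from .structure.interface import InterfaceDefinition, interface_residues
from .structure.model import ResidueKey, StructureModel
from .structure.rotamers import (
    AA1_TO_3,
    RotamerLibrary,
    default_rotamer_library,
    enumerate_rotamers,
)
from .structure.sasa import relative_sasa

__all__ = [
    "MutationRecord", "ScreenParams", "InterfaceFlag", "MutationAssessment",
    "ScreenSummary", "assess_mutation", "screen",
    "read_mutation_table", "CATEGORIES",
]

CATEGORIES = (
    "unstable",
    "hbond_loss_unstable",
    "interface_altering",
    "pathogenic_unknown",
    "no_predicted_effect",
)

_CANONICAL = set(AA1_TO_3)


@dataclass(frozen=True)
class MutationRecord:
    wt_aa: str
    position: int
    mut_aa: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.wt_aa not in _CANONICAL or self.mut_aa not in _CANONICAL:
            raise ValueError(f"non-canonical amino acid in {self.label}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"{self.label}: wild-type equals mutant")
        if not 1 <= self.position:
            raise ValueError(f"{self.label}: position must be ≥ 1")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def change(self) -> Tuple[str, int, str]:
        return (self.wt_aa, self.position, self.mut_aa)


@dataclass
class ScreenParams:
    overlap_tolerance: float = 0.4      # Å of allowed vdW interpenetration
    surface_threshold: float = 0.2      # relative SASA cutoff for "surface"
    hbond_cutoff: float = 3.5           # Å, donor–acceptor heavy atoms
    salt_cutoff: float = 4.0            # Å, charged-group heavy atoms
    sasa_points: int = 196              # Shrake–Rupley sphere points
    probe_radius: float = 1.4           # Å
    seq_length: int = 610               # menin protein length
    menin_chain: Optional[str] = None   # default: first chain of the monomer


@dataclass(frozen=True)
class InterfaceFlag:
    interface: str
    within_radius: bool
    predicted_effect: str               # "none" | "disrupt" | "possible_gain"


@dataclass
class MutationAssessment:
    mutation: MutationRecord
    in_structure: bool
    surface_accessible: bool = False
    relative_sasa: float = float("nan")
    n_rotamers: int = 0
    clash_fraction: float = 0.0
    stability_class: str = "stable"
    hbond_loss: int = 0
    salt_bridge_loss: int = 0
    interface_flags: List[InterfaceFlag] = field(default_factory=list)
    overall_category: str = "pathogenic_unknown"

    def to_row(self) -> Dict[str, object]:
        row: Dict[str, object] = {
            "mutation": self.mutation.label,
            "wt_aa": self.mutation.wt_aa,
            "position": self.mutation.position,
            "mut_aa": self.mutation.mut_aa,
            "source": self.mutation.source,
            "in_structure": self.in_structure,
            "surface_accessible": self.surface_accessible,
            "relative_sasa": self.relative_sasa,
            "n_rotamers": self.n_rotamers,
            "clash_fraction": self.clash_fraction,
            "stability_class": self.stability_class,
            "hbond_loss": self.hbond_loss,
            "salt_bridge_loss": self.salt_bridge_loss,
            "overall_category": self.overall_category,
        }
        for flag in self.interface_flags:
            row[f"if_{flag.interface}_within"] = flag.within_radius
            row[f"if_{flag.interface}_effect"] = flag.predicted_effect
        return row


@dataclass
class ScreenSummary:
    assessments: List[MutationAssessment]
    category_counts_rows: Dict[str, int]
    category_counts_unique: Dict[str, int]
    n_rows: int
    n_unique_changes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([a.to_row() for a in self.assessments])

    def summary(self) -> Dict[str, object]:
        return {
            "n_rows": self.n_rows,
            "n_unique_changes": self.n_unique_changes,
            "category_counts_rows": dict(self.category_counts_rows),
            "category_counts_unique": dict(self.category_counts_unique),
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def _lost_roles(wt3: str, mut3: str) -> Dict[str, bool]:
    wt = sidechain_capabilities(wt3)
    mut = sidechain_capabilities(mut3)
    return {role: wt[role] and not mut[role] for role in wt}


def _gained_roles(wt3: str, mut3: str) -> Dict[str, bool]:
    wt = sidechain_capabilities(wt3)
    mut = sidechain_capabilities(mut3)
    return {role: mut[role] and not wt[role] for role in wt}


def assess_mutation(
    mutation: MutationRecord,
    monomer: StructureModel,
    complexes: Sequence[Tuple[StructureModel, InterfaceDefinition]] = (),
    library: Optional[RotamerLibrary] = None,
    params: Optional[ScreenParams] = None,
    _sasa: Optional[Dict[ResidueKey, float]] = None,
    _interface_sets: Optional[Dict[str, set]] = None,
) -> MutationAssessment:
    """Full assessment of one missense mutation.

    ``_sasa`` / ``_interface_sets`` accept precomputed per-structure maps so
    :func:`screen` can amortize them across mutations.
    """
    params = params or ScreenParams()
    library = library if library is not None else default_rotamer_library()
    if not 1 <= mutation.position <= params.seq_length:
        raise ValueError(
            f"{mutation.label}: position outside 1–{params.seq_length}"
        )

    chain = params.menin_chain or monomer.chains[0]
    key: ResidueKey = (chain, mutation.position, "")
    if key not in monomer.residue_index:
        return MutationAssessment(
            mutation=mutation, in_structure=False,
            overall_category="pathogenic_unknown",
        )

    wt3 = monomer.residue_name(key)
    mut3 = AA1_TO_3[mutation.mut_aa]

    # surface accessibility
    sasa_map = _sasa if _sasa is not None else relative_sasa(
        monomer, params.probe_radius, params.sasa_points
    )
    rel = sasa_map.get(key, float("nan"))
    surface = bool(rel >= params.surface_threshold) if not math.isnan(rel) else False

    # rotamer clash criterion
    chi_sets = library.get(mutation.mut_aa, [])
    n_rot = len(chi_sets)
    if n_rot == 0:
        frac, stability = 0.0, "stable"       # Gly/Ala: criterion cannot fire
    else:
        placements = enumerate_rotamers(monomer, key, mutation.mut_aa, library)
        frac, stability = _clash_fraction(placements, monomer, params.overlap_tolerance)

    # polar-contact losses
    contacts = hydrogen_bonds(monomer, key, params.hbond_cutoff, params.salt_cutoff)
    lost = _lost_roles(wt3, mut3)
    hb_loss = sum(
        1 for c in contacts if c.kind == "hbond" and lost.get(c.self_role, False)
    )
    sb_loss = sum(
        1 for c in contacts if c.kind == "salt_bridge" and lost.get(c.self_role, False)
    )

    # interface zones
    gained = _gained_roles(wt3, mut3)
    wt_caps = sidechain_capabilities(wt3)
    flags: List[InterfaceFlag] = []
    for cmodel, idef in complexes:
        if _interface_sets is not None and idef.name in _interface_sets:
            zone = _interface_sets[idef.name]
        else:
            zone = interface_residues(cmodel, idef)
        within = any(
            (mchain, mutation.position, "") in zone for mchain in idef.menin_chains
        )
        effect = "none"
        if within and surface:
            if wt_caps["donor"] or wt_caps["acceptor"]:
                if any(lost.values()):
                    effect = "disrupt"
                elif any(gained.values()):
                    effect = "possible_gain"
            elif any(gained.values()):
                effect = "possible_gain"
        flags.append(InterfaceFlag(idef.name, within, effect))

    # category precedence
    if stability == "unstable":
        category = "unstable"
    elif hb_loss + sb_loss > 0:
        category = "hbond_loss_unstable"
    elif any(f.predicted_effect != "none" for f in flags):
        category = "interface_altering"
    else:
        category = "no_predicted_effect"

    return MutationAssessment(
        mutation=mutation,
        in_structure=True,
        surface_accessible=surface,
        relative_sasa=float(rel),
        n_rotamers=n_rot,
        clash_fraction=frac,
        stability_class=stability,
        hbond_loss=hb_loss,
        salt_bridge_loss=sb_loss,
        interface_flags=flags,
        overall_category=category,
    )


def screen(
    mutations: Sequence[MutationRecord],
    monomer: StructureModel,
    complexes: Sequence[Tuple[StructureModel, InterfaceDefinition]] = (),
    library: Optional[RotamerLibrary] = None,
    params: Optional[ScreenParams] = None,
) -> ScreenSummary:
    """Assess a mutation list; per-structure maps are computed once."""
    if not mutations:
        raise ValueError("empty mutation list")
    params = params or ScreenParams()
    sasa_map = relative_sasa(monomer, params.probe_radius, params.sasa_points)
    iface_sets = {
        idef.name: interface_residues(cmodel, idef) for cmodel, idef in complexes
    }

    assessments = [
        assess_mutation(
            m, monomer, complexes, library, params,
            _sasa=sasa_map, _interface_sets=iface_sets,
        )
        for m in mutations
    ]

    row_counts: Counter = Counter(a.overall_category for a in assessments)
    seen: Dict[Tuple[str, int, str], str] = {}
    for a in assessments:
        seen.setdefault(a.mutation.change, a.overall_category)
    unique_counts: Counter = Counter(seen.values())

    return ScreenSummary(
        assessments=assessments,
        category_counts_rows={c: row_counts.get(c, 0) for c in CATEGORIES},
        category_counts_unique={c: unique_counts.get(c, 0) for c in CATEGORIES},
        n_rows=len(assessments),
        n_unique_changes=len(seen),
    )


def read_mutation_table(tsv_text: str) -> List[MutationRecord]:
    """Parse a mutation list TSV with columns wt_aa, position, mut_aa, source."""
    from io import StringIO

    df = pd.read_csv(StringIO(tsv_text), sep="\t", dtype=str)
    required = {"wt_aa", "position", "mut_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            MutationRecord(
                wt_aa=str(row["wt_aa"]).strip(),
                position=int(row["position"]),
                mut_aa=str(row["mut_aa"]).strip(),
                source=str(row.get("source", "") or ""),
            )
        )
    return records
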