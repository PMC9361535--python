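"""iBAQ interaction stoichiometry and complex-recovery summaries.

Per protein and pull-down replicate, the mean control iBAQ is subtracted
(clamped at zero) and the background-subtracted value is expressed
relative to the bait, whose stoichiometry is 1 by construction.  Mutant
complex recovery is the mean over complex members of the mutant/wild-type
stoichiometry ratio, with members absent from the mutant counted as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .io import ProteinGroupTable, SampleDesign

__all__ = [
    "StoichiometryTable", "ComplexDefinition", "DEFAULT_COMPLEXES",
    "ibaq_stoichiometry", "complex_recovery",
]

#: COMPASS-like MLL1/MLL2 methyltransferase subunits and the JunD/AP-1 set
DEFAULT_COMPLEXES: Dict[str, Set[str]] = {
    "MLL1/MLL2": {
        "DPY30", "KMT2A", "KMT2B", "WDR5", "ASH2L", "RBBP5",
        "HCFC1", "HCFC2", "PSIP1",
    },
    "JunD": {"JUND", "ATF7", "FOS"},
}


@dataclass
class ComplexDefinition:
    complexes: Dict[str, Set[str]] = field(
        default_factory=lambda: {k: set(v) for k, v in DEFAULT_COMPLEXES.items()}
    )


@dataclass
class StoichiometryTable:
    """Bait-normalized background-subtracted iBAQ stoichiometries."""

    frame: pd.DataFrame               # index: protein id; gene, adj_ibaq, stoich, sd
    bait_id: str

    def stoich_by_gene(self) -> pd.Series:
        s = self.frame.set_index("gene")["stoich"]
        return s[~s.index.duplicated()]

    def summary(self) -> pd.DataFrame:
        return self.frame.sort_values("stoich", ascending=False)


def _match_bait(table: ProteinGroupTable, bait_id: str) -> int:
    hits = [
        i for i, (pid, gene) in enumerate(zip(table.ids, table.gene_names))
        if bait_id == pid or bait_id in str(pid).split(";")
        or bait_id == gene or bait_id in str(gene).split(";")
    ]
    if not hits:
        raise ValueError(f"bait {bait_id!r} not found in table")
    return hits[0]


def ibaq_stoichiometry(
    table: ProteinGroupTable,
    design: SampleDesign,
    bait_id: str,
    pulldown_group: Optional[str] = None,
) -> StoichiometryTable:
    """Stoichiometry of every protein relative to the bait.

    Missing iBAQ values are treated as zero intensity (not detected).
    Raises ``ValueError("bait not recovered")`` when the bait's
    background-subtracted iBAQ is not positive.
    """
    groups = design.groups
    g_pull = pulldown_group or groups[0]
    g_ctrl = [g for g in groups if g != g_pull][0]
    pull_samples = design.samples(g_pull)
    ctrl_samples = design.samples(g_ctrl)

    ibaq = table.ibaq.fillna(0.0)
    ctrl_mean = ibaq[ctrl_samples].mean(axis=1)
    adj = ibaq[pull_samples].sub(ctrl_mean, axis=0).clip(lower=0.0)  # per replicate

    bait_row = _match_bait(table, bait_id)
    bait_adj = adj.iloc[bait_row]
    if float(bait_adj.mean()) <= 0:
        raise ValueError("bait not recovered")

    stoich = adj.mean(axis=1) / float(bait_adj.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = adj.div(bait_adj.values, axis=1)
    sd = ratios.std(axis=1, ddof=1)

    frame = pd.DataFrame(
        {
            "gene": table.gene_names.values,
            "adj_ibaq": adj.mean(axis=1).values,
            "stoich": stoich.values,
            "sd": sd.values,
        },
        index=table.ids,
    )
    return StoichiometryTable(frame=frame, bait_id=bait_id)


def complex_recovery(
    stoich_mutant: StoichiometryTable,
    stoich_wt: StoichiometryTable,
    complexes: Optional[ComplexDefinition] = None,
) -> pd.DataFrame:
    """Per-complex recovery of the mutant relative to wild type.

    Returns a frame indexed by complex name with columns ``recovery``
    (mean member-wise mutant/WT stoichiometry ratio), ``sd`` (dispersion
    over members) and ``n_members``.
    """
    complexes = complexes or ComplexDefinition()
    wt = stoich_wt.stoich_by_gene()
    mut = stoich_mutant.stoich_by_gene()

    rows = []
    for name, members in complexes.complexes.items():
        present = [g for g in sorted(members) if g in wt.index and wt[g] > 0]
        if not present:
            raise ValueError(f"complex {name!r} has no members recovered in WT")
        ratios = np.array(
            [float(mut.get(g, 0.0)) / float(wt[g]) for g in present]
        )
        rows.append(
            {
                "complex": name,
                "recovery": float(ratios.mean()),
                "sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
                "n_members": len(present),
            }
        )
    return pd.DataFrame(rows).set_index("complex")
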