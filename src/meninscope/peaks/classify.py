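"""Eight-way co-occupancy classification of menin peaks.

Each menin peak gets three booleans — overlaps MLL1, overlaps JunD,
overlaps H3K4me3 — where overlap means ≥1 bp intersection with the merged
partner set.  The three bits form category codes 0–7 (MLL1 bit 4, JunD
bit 2, H3K4me3 bit 1).  A configurable grouping collapses the eight codes
into display clusters; the default preset mirrors the six-cluster layout
used for co-occupancy heatmaps, with the two MLL1⁻/JunD⁻ categories
reported separately as "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .intervals import PeakSet

__all__ = ["CategoryCode", "ClassificationResult", "classify_peaks",
           "SIX_CLUSTER_PRESET", "category_label"]


def category_label(code: int) -> str:
    m = "+" if code & 4 else "-"
    j = "+" if code & 2 else "-"
    k = "+" if code & 1 else "-"
    return f"M{m}J{j}K{k}"


#: code → display cluster, mirroring the six-cluster co-occupancy layout
SIX_CLUSTER_PRESET: Dict[int, str] = {
    0b111: "c1",   # MLL1+ JunD+ K4me3+
    0b110: "c2",   # MLL1+ JunD+ K4me3-
    0b011: "c3",   # MLL1- JunD+ K4me3+
    0b010: "c4",   # MLL1- JunD+ K4me3-
    0b101: "c5",   # MLL1+ JunD- K4me3+
    0b100: "c6",   # MLL1+ JunD- K4me3-
    0b001: "other",
    0b000: "other",
}

RAW_PRESET: Dict[int, str] = {c: category_label(c) for c in range(8)}

CategoryCode = int


@dataclass
class ClassificationResult:
    frame: pd.DataFrame               # chrom, start, end, mll1, jund, k4me3, code, cluster
    counts: Dict[int, int]
    percentages: Dict[int, float]
    cluster_counts: Dict[str, int]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "code": c,
                "category": category_label(c),
                "count": self.counts.get(c, 0),
                "percent": self.percentages.get(c, 0.0),
            }
            for c in range(8)
        ]
        return pd.DataFrame(rows)


def _overlap_flags(peaks: PeakSet, partner: PeakSet) -> np.ndarray:
    """Boolean ≥1 bp overlap of each peak with the merged partner set."""
    merged = partner.merged().by_chrom()
    flags = np.zeros(len(peaks), bool)
    for i, iv in enumerate(peaks):
        if iv.chrom not in merged:
            continue
        starts, ends = merged[iv.chrom]
        idx = int(np.searchsorted(starts, iv.end, side="left"))
        # merged intervals are disjoint and sorted, so ends are increasing
        flags[i] = idx > 0 and ends[idx - 1] > iv.start
    return flags


def classify_peaks(
    menin: PeakSet,
    mll1: PeakSet,
    jund: PeakSet,
    k4me3: PeakSet,
    cluster_preset: Optional[Dict[int, str]] = None,
) -> ClassificationResult:
    """Assign every menin peak to one of the 8 co-occupancy categories."""
    if len(menin) == 0:
        raise ValueError("menin peak set is empty")
    partner_chroms = (
        set(mll1.chromosomes()) | set(jund.chromosomes()) | set(k4me3.chromosomes())
    )
    if partner_chroms and not (set(menin.chromosomes()) & partner_chroms):
        raise ValueError(
            "no shared chromosome names between menin and partner peak sets"
        )
    preset = cluster_preset or SIX_CLUSTER_PRESET

    m = _overlap_flags(menin, mll1)
    j = _overlap_flags(menin, jund)
    k = _overlap_flags(menin, k4me3)
    codes = 4 * m.astype(int) + 2 * j.astype(int) + k.astype(int)

    frame = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in menin],
            "start": [iv.start for iv in menin],
            "end": [iv.end for iv in menin],
            "mll1": m,
            "jund": j,
            "k4me3": k,
            "code": codes,
            "cluster": [preset.get(int(c), "other") for c in codes],
        }
    )
    counts = {c: int((codes == c).sum()) for c in range(8)}
    total = len(menin)
    percentages = {c: 100.0 * counts[c] / total for c in range(8)}
    cluster_counts = frame["cluster"].value_counts().to_dict()
    return ClassificationResult(
        frame=frame,
        counts=counts,
        percentages=percentages,
        cluster_counts={k_: int(v) for k_, v in cluster_counts.items()},
    )
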