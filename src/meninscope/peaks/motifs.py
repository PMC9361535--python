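"""AP-1 / ATF consensus motif annotation of peaks.

Two fixed IUPAC consensus motifs are scanned on both strands:
AP-1 ``TGASTCA`` (S = C or G) and ATF/CRE ``TGACGTCA``.  For disjoint
pie-chart style proportions the precedence is ATF > AP-1: a peak whose
only hit also matches the degenerate AP-1 pattern through a ``TGACGTCA``
core is counted as ATF.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Union

import pandas as pd

from .intervals import PeakSet

__all__ = ["MotifModel", "motif_annotate", "reverse_complement"]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(_IUPAC[c] for c in pattern.upper()))


@dataclass
class MotifModel:
    ap1: str = "TGASTCA"
    atf: str = "TGACGTCA"

    def matches(self, seq: str, pattern: str) -> bool:
        """Strand-symmetric match of an IUPAC consensus in ``seq``."""
        rx = _iupac_regex(pattern)
        seq = seq.upper()
        return bool(rx.search(seq) or rx.search(reverse_complement(seq)))


GenomeSource = Mapping[str, object]   # chrom → str-like sequence (dict or pyfaidx.Fasta)


def _fetch(genome: GenomeSource, chrom: str, start: int, end: int) -> str:
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = genome[chrom]
    n = len(seq)
    if start < 0 or end > n:
        raise ValueError(f"peak {chrom}:{start}-{end} outside genome bounds (len {n})")
    return str(seq[start:end])


def motif_annotate(
    peaks: PeakSet,
    genome: GenomeSource,
    motifs: Optional[MotifModel] = None,
    categories: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-peak AP-1 / ATF flags and the disjoint pie assignment.

    Returns a frame with columns ``ap1``, ``atf`` (raw strand-symmetric
    hits) and ``assignment`` ∈ {"ATF", "AP-1", "other"} (precedence
    ATF > AP-1).  If ``categories`` (aligned with peak order) is given, a
    ``category`` column is attached for per-category proportion summaries.
    """
    motifs = motifs or MotifModel()
    rows = []
    for iv in peaks:
        seq = _fetch(genome, iv.chrom, iv.start, iv.end)
        ap1 = motifs.matches(seq, motifs.ap1)
        atf = motifs.matches(seq, motifs.atf)
        assignment = "ATF" if atf else ("AP-1" if ap1 else "other")
        rows.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "ap1": ap1, "atf": atf, "assignment": assignment,
            }
        )
    frame = pd.DataFrame(rows)
    if categories is not None:
        frame["category"] = list(categories)
    return frame


def motif_proportions(annotated: pd.DataFrame, by: Optional[str] = None) -> pd.DataFrame:
    """Percentage of peaks assigned ATF / AP-1 / other (optionally per group)."""
    def _prop(df: pd.DataFrame) -> pd.Series:
        n = len(df)
        return pd.Series(
            {
                "ATF": 100.0 * (df["assignment"] == "ATF").sum() / n,
                "AP-1": 100.0 * (df["assignment"] == "AP-1").sum() / n,
                "other": 100.0 * (df["assignment"] == "other").sum() / n,
                "n": n,
            }
        )

    if by is None:
        return _prop(annotated).to_frame().T
    return annotated.groupby(by, group_keys=True).apply(_prop, include_groups=False)
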