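"""Genomic interval sets (BED semantics: 0-based, half-open)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

__all__ = ["GenomicInterval", "PeakSet", "read_intervals", "write_intervals"]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """Per-chromosome-sorted intervals with a factor label."""

    intervals: List[GenomicInterval]
    label: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chromosomes(self) -> List[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """chrom → (starts, ends) arrays, sorted by start."""
        out: Dict[str, Tuple[list, list]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, ([], []))
            out[iv.chrom][0].append(iv.start)
            out[iv.chrom][1].append(iv.end)
        return {
            c: (np.asarray(s, int), np.asarray(e, int)) for c, (s, e) in out.items()
        }

    def merged(self) -> "PeakSet":
        """Union of overlapping/adjacent intervals (scores dropped)."""
        merged: List[GenomicInterval] = []
        for chrom, (starts, ends) in self.by_chrom().items():
            cur_s, cur_e = None, None
            for s, e in zip(starts, ends):
                if cur_s is None:
                    cur_s, cur_e = int(s), int(e)
                elif s <= cur_e:
                    cur_e = max(cur_e, int(e))
                else:
                    merged.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = int(s), int(e)
            if cur_s is not None:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
        return PeakSet(merged, label=self.label)


def read_intervals(bed_text: str, label: str = "") -> PeakSet:
    """Parse BED3+ text; raises with the line number on malformed input."""
    intervals: List[GenomicInterval] = []
    for lineno, line in enumerate(bed_text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"line {lineno}: need ≥3 columns, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric coordinates") from None
        if start >= end:
            raise ValueError(f"line {lineno}: start ≥ end ({start} ≥ {end})")
        score = None
        if len(fields) >= 5:
            try:
                score = float(fields[4])
            except ValueError:
                score = None
        intervals.append(GenomicInterval(fields[0], start, end, score))
    return PeakSet(intervals, label=label)


def write_intervals(peaks: PeakSet) -> str:
    """Serialize sorted BED text (name column carries the label)."""
    lines = []
    for i, iv in enumerate(peaks.intervals):
        name = f"{peaks.label or 'peak'}_{i + 1}"
        score = 0 if iv.score is None else iv.score
        lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}")
    return "\n".join(lines) + ("\n" if lines else "")
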