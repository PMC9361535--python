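"""Binned coverage tracks: IO, per-peak quantification, correlation, heatmaps.

A :class:`CoverageTrack` stores fixed-step binned signal per chromosome;
the value of a bin is the mean per-base signal over that bin, matching the
bedGraph convention when segments are written out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import PeakSet

__all__ = [
    "CoverageTrack", "quantify_peak_coverage", "binned_correlation",
    "tornado_matrix",
]


@dataclass
class CoverageTrack:
    """Fixed-step per-chromosome signal."""

    signal: Dict[str, np.ndarray]     # chrom → per-bin values (≥ 0)
    bin_size: int
    label: str = ""
    norm_factor: float = 1.0          # factor already applied to the signal

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin size must be > 0")
        self.signal = {c: np.asarray(v, float) for c, v in self.signal.items()}
        for c, v in self.signal.items():
            if (v < 0).any():
                raise ValueError(f"negative signal on {c}")

    def scaled(self, factor: float) -> "CoverageTrack":
        """Return a copy with all bins multiplied by ``factor``."""
        return CoverageTrack(
            signal={c: v * factor for c, v in self.signal.items()},
            bin_size=self.bin_size,
            label=self.label,
            norm_factor=self.norm_factor * factor,
        )

    def rebinned(self, bin_size: int) -> "CoverageTrack":
        """Aggregate to a coarser bin (signal-weighted mean per new bin)."""
        if bin_size % self.bin_size != 0:
            raise ValueError("new bin size must be a multiple of the current one")
        k = bin_size // self.bin_size
        out = {}
        for c, v in self.signal.items():
            pad = (-len(v)) % k
            vv = np.pad(v, (0, pad))
            out[c] = vv.reshape(-1, k).mean(axis=1)
        return CoverageTrack(out, bin_size, self.label, self.norm_factor)

    def value_at(self, chrom: str, pos: int) -> float:
        v = self.signal.get(chrom)
        if v is None:
            return 0.0
        b = pos // self.bin_size
        return float(v[b]) if 0 <= b < len(v) else 0.0

    # -- bedGraph IO -------------------------------------------------------
    def to_bedgraph(self) -> str:
        lines = []
        for chrom in sorted(self.signal):
            v = self.signal[chrom]
            for b, val in enumerate(v):
                if val != 0:
                    lines.append(
                        f"{chrom}\t{b * self.bin_size}\t{(b + 1) * self.bin_size}\t{val:g}"
                    )
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_bedgraph(
        cls, text: str, bin_size: int, chrom_sizes: Dict[str, int], label: str = ""
    ) -> "CoverageTrack":
        """Read bedGraph text onto a fixed grid (mean per-base value per bin)."""
        sums = {
            c: np.zeros(-(-size // bin_size)) for c, size in chrom_sizes.items()
        }
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"bedGraph line {lineno}: need 4 columns")
            chrom, start, end, val = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in sums:
                continue
            arr = sums[chrom]
            for b in range(start // bin_size, -(-end // bin_size)):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                if hi > lo and b < len(arr):
                    arr[b] += val * (hi - lo)
        signal = {c: v / bin_size for c, v in sums.items()}
        return cls(signal, bin_size, label=label)


def quantify_peak_coverage(
    peaks: PeakSet, track: CoverageTrack, mode: str = "sum"
) -> np.ndarray:
    """Per-peak signal: sum (default) or mean of per-base values."""
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    bs = track.bin_size
    out = np.zeros(len(peaks))
    for i, iv in enumerate(peaks):
        v = track.signal.get(iv.chrom)
        if v is None:
            continue
        total = 0.0
        for b in range(iv.start // bs, -(-iv.end // bs)):
            if b >= len(v):
                break
            lo = max(iv.start, b * bs)
            hi = min(iv.end, (b + 1) * bs)
            if hi > lo:
                total += v[b] * (hi - lo)
        out[i] = total / iv.length if mode == "mean" else total
    return out


def binned_correlation(
    tracks: Sequence[CoverageTrack],
    bin_size: int = 10_000,
    drop_zero_bins: bool = True,
) -> pd.DataFrame:
    """Pearson correlation matrix of tracks at ``bin_size`` resolution.

    Bins with zero signal in every track are dropped (configurable);
    constant tracks yield ``NaN`` correlations, never 0.
    """
    if len(tracks) < 2:
        raise ValueError("need ≥2 tracks")
    chroms = set(tracks[0].signal)
    for t in tracks[1:]:
        chroms &= set(t.signal)
    if not chroms:
        raise ValueError("tracks share no chromosomes")

    columns = []
    for t in tracks:
        rb = t.rebinned(bin_size) if t.bin_size != bin_size else t
        col = np.concatenate([rb.signal[c] for c in sorted(chroms)])
        columns.append(col)
    n = min(len(c) for c in columns)
    mat = np.vstack([c[:n] for c in columns])
    if drop_zero_bins:
        keep = mat.sum(axis=0) > 0
        mat = mat[:, keep]

    labels = [t.label or f"track{i}" for i, t in enumerate(tracks)]
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = mat.std(axis=1)
        corr = np.corrcoef(mat)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, [1.0 if s > 0 else np.nan for s in sd])
    return pd.DataFrame(corr, index=labels, columns=labels)


def tornado_matrix(
    peaks: PeakSet,
    track: CoverageTrack,
    flank: int = 2000,
    nbins: int = 40,
) -> Tuple[np.ndarray, np.ndarray]:
    """Peaks × bins signal matrix centered on peak midpoints.

    Returns ``(matrix, order)`` where rows are sorted by total signal
    descending and ``order`` maps rows back to peak indices.
    """
    if flank <= 0 or nbins <= 0:
        raise ValueError("flank and nbins must be > 0")
    width = 2 * flank / nbins
    mat = np.zeros((len(peaks), nbins))
    for i, iv in enumerate(peaks):
        mid = iv.midpoint
        for b in range(nbins):
            lo = mid - flank + b * width
            hi = lo + width
            # mean per-base signal over [lo, hi)
            vals = [
                track.value_at(iv.chrom, int(p))
                for p in np.arange(lo, hi, track.bin_size)
                if p >= 0
            ]
            mat[i, b] = float(np.mean(vals)) if vals else 0.0
    order = np.argsort(-mat.sum(axis=1), kind="stable")
    return mat[order], order
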