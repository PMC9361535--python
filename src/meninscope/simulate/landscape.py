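"""Synthetic genome-occupancy landscapes with known ground truth.

Emulates the inputs of the occupancy analysis: menin/MLL1/JunD/H3K4me3
peak sets realizing a configured mixture over the eight co-occupancy
categories exactly (after rounding), a motif-bearing genome sequence
(AP-1/ATF consensus injected at configured rates into JunD⁺ peaks, and
scrubbed from the random background so motif truth is exact), Poisson
read-count coverage tracks per genotype, spike-in read counts at exact
configured ratios, and per-genotype planted binding loss (a fraction of
the peaks of a target cluster scaled to a residual signal fraction).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ..peaks.classify import SIX_CLUSTER_PRESET
from ..peaks.coverage import CoverageTrack
from ..peaks.intervals import GenomicInterval, PeakSet
from ..peaks.spikein import SpikeInStats

__all__ = ["LandscapeSpec", "LandscapeTruth", "LandscapeData", "simulate_peak_landscape"]

_AP1_RE = re.compile("TGA[CG]TCA")      # covers both strands (revcomp maps onto itself)
_ATF_RE = re.compile("TGACGTCA")        # palindromic

#: default mixture over category codes (M bit 4, J bit 2, K bit 1)
DEFAULT_MIXTURE: Dict[int, float] = {
    0b111: 0.50, 0b110: 0.08, 0b011: 0.09, 0b010: 0.06,
    0b101: 0.15, 0b100: 0.05, 0b001: 0.04, 0b000: 0.03,
}


@dataclass
class LandscapeSpec:
    chrom_count: int = 2
    chrom_length: int = 400_000
    n_menin_peaks: int = 300
    peak_width: int = 600
    width_jitter: int = 150
    category_mixture: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE)
    )
    bin_size: int = 50
    background_rate: float = 0.05     # reads per base
    peak_rate: float = 3.0            # added reads per base inside a peak
    ap1_rate: float = 0.5             # P(AP-1 motif) inside a JunD+ peak
    atf_rate: float = 0.15            # P(ATF motif) inside a JunD+ peak
    #: genotype → (cluster, fraction of that cluster's peaks lost, residual signal)
    mutant_loss: Dict[str, List[Tuple[str, float, float]]] = field(default_factory=dict)
    #: sample → (target_reads, spike_reads)
    spike_reads: Dict[str, Tuple[int, int]] = field(default_factory=dict)


@dataclass
class LandscapeTruth:
    codes: np.ndarray                 # per menin peak, aligned with the sorted PeakSet
    clusters: List[str]
    motif_assignment: List[str]       # "ATF" | "AP-1" | "other"
    lost: Dict[str, np.ndarray]       # genotype → bool per peak


@dataclass
class LandscapeData:
    peak_sets: Dict[str, PeakSet]     # menin, mll1, jund, k4me3
    tracks: Dict[str, CoverageTrack]  # genotype → track ("WT" plus mutants)
    spike_stats: Dict[str, SpikeInStats]
    genome: Dict[str, str]
    truth: LandscapeTruth


def _exact_counts(mixture: Dict[int, float], n: int) -> Dict[int, int]:
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise ValueError("category mixture proportions must sum to 1")
    raw = {c: p * n for c, p in mixture.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def _scrub_motifs(seq: np.ndarray, rng: np.random.Generator) -> None:
    """Mutate accidental AP-1/ATF matches in-place until none remain."""
    for _ in range(20):
        s = "".join(seq)
        hits = [m.start() for m in _AP1_RE.finditer(s)]
        hits += [m.start() for m in _ATF_RE.finditer(s)]
        if not hits:
            return
        for h in hits:
            seq[h + 2] = rng.choice(list("CT"))  # break the TGA core
    raise RuntimeError("motif scrubbing did not converge")


def simulate_peak_landscape(
    spec: LandscapeSpec, seed: int = 0
) -> LandscapeData:
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(spec.chrom_count)]

    # --- peak placement (regular spacing + jitter → never overlapping) ----
    per_chrom = np.full(spec.chrom_count, spec.n_menin_peaks // spec.chrom_count)
    per_chrom[: spec.n_menin_peaks % spec.chrom_count] += 1
    max_width = spec.peak_width + spec.width_jitter
    footprint = int(per_chrom.max()) * max_width * 3
    if spec.chrom_length < footprint:
        raise ValueError(
            f"chromosome length {spec.chrom_length} too small for "
            f"{int(per_chrom.max())} peaks of width ≤ {max_width}"
        )

    menin: List[GenomicInterval] = []
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        spacing = spec.chrom_length // (n + 1)
        for i in range(n):
            width = spec.peak_width + int(rng.integers(-spec.width_jitter,
                                                       spec.width_jitter + 1))
            center = (i + 1) * spacing + int(rng.integers(-spacing // 6, spacing // 6))
            start = max(0, center - width // 2)
            menin.append(GenomicInterval(chrom, start, start + width))
    menin_set = PeakSet(menin, label="menin")     # sorted construction order preserved

    # --- exact category realization --------------------------------------
    counts = _exact_counts(spec.category_mixture, len(menin_set))
    codes = np.concatenate([np.full(k, c, int) for c, k in counts.items()])
    codes = rng.permutation(codes)

    partner_sets: Dict[str, List[GenomicInterval]] = {"mll1": [], "jund": [], "k4me3": []}
    bit = {"mll1": 4, "jund": 2, "k4me3": 1}
    for iv, code in zip(menin_set, codes):
        for factor, b in bit.items():
            if code & b:
                off = int(rng.integers(-iv.length // 4, iv.length // 4 + 1))
                partner_sets[factor].append(
                    GenomicInterval(iv.chrom, max(0, iv.start + off), iv.end + off)
                )

    peak_sets = {"menin": menin_set}
    for factor, ivs in partner_sets.items():
        peak_sets[factor] = PeakSet(ivs, label=factor)

    # --- genome sequence with exact motif truth ---------------------------
    genome: Dict[str, str] = {}
    seq_arrays = {
        c: rng.choice(list("ACGT"), size=spec.chrom_length) for c in chroms
    }
    for arr in seq_arrays.values():
        _scrub_motifs(arr, rng)

    motif_assignment: List[str] = []
    for iv, code in zip(menin_set, codes):
        assignment = "other"
        if code & 2:  # JunD+ peaks carry motifs at the configured rates
            u = rng.random()
            if u < spec.atf_rate:
                assignment = "ATF"
            elif u < spec.atf_rate + spec.ap1_rate:
                assignment = "AP-1"
        if assignment == "ATF":
            motif = "TGACGTCA"
        elif assignment == "AP-1":
            motif = "TGACTCA" if rng.random() < 0.5 else "TGAGTCA"
        else:
            motif = None
        if motif:
            pos = iv.midpoint - len(motif) // 2
            seq_arrays[iv.chrom][pos: pos + len(motif)] = list(motif)
        motif_assignment.append(assignment)
    genome = {c: "".join(a) for c, a in seq_arrays.items()}

    # --- per-genotype coverage with planted loss --------------------------
    clusters = [SIX_CLUSTER_PRESET[int(c)] for c in codes]
    n_bins = -(-spec.chrom_length // spec.bin_size)
    genotypes = ["WT"] + list(spec.mutant_loss)
    lost: Dict[str, np.ndarray] = {}
    tracks: Dict[str, CoverageTrack] = {}
    for g in genotypes:
        lost_mask = np.zeros(len(menin_set), bool)
        residual = np.ones(len(menin_set))
        if g != "WT":
            for cluster, frac, resid in spec.mutant_loss[g]:
                members = np.flatnonzero(np.array(clusters) == cluster)
                k = int(round(frac * len(members)))
                chosen = rng.choice(members, size=k, replace=False)
                lost_mask[chosen] = True
                residual[chosen] = resid
        rate = {c: np.full(n_bins, spec.background_rate) for c in chroms}
        for idx, iv in enumerate(menin_set):
            b0 = iv.start // spec.bin_size
            b1 = -(-iv.end // spec.bin_size)
            rate[iv.chrom][b0:b1] += spec.peak_rate * residual[idx]
        signal = {
            c: rng.poisson(r * spec.bin_size).astype(float) / spec.bin_size
            for c, r in rate.items()
        }
        tracks[g] = CoverageTrack(signal, spec.bin_size, label=g)
        if g != "WT":
            lost[g] = lost_mask

    spike_stats = {
        s: SpikeInStats(s, target, spike, target + spike)
        for s, (target, spike) in spec.spike_reads.items()
    }

    truth = LandscapeTruth(
        codes=codes,
        clusters=clusters,
        motif_assignment=motif_assignment,
        lost=lost,
    )
    return LandscapeData(
        peak_sets=peak_sets,
        tracks=tracks,
        spike_stats=spike_stats,
        genome=genome,
        truth=truth,
    )
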