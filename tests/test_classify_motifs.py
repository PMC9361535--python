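"""Co-occupancy classification and motif annotation."""

import numpy as np
import pytest

from meninscope.peaks.classify import SIX_CLUSTER_PRESET, category_label, classify_peaks
from meninscope.peaks.intervals import GenomicInterval, PeakSet
from meninscope.peaks.motifs import MotifModel, motif_annotate, reverse_complement


def _ps(triples, label=""):
    return PeakSet([GenomicInterval(c, s, e) for c, s, e in triples], label=label)


def test_single_peak_code_by_definition():
    menin = _ps([("chr1", 100, 200)])
    mll1 = _ps([("chr1", 150, 250)])
    jund = _ps([])
    k4 = _ps([("chr1", 0, 1000)])
    res = classify_peaks(menin, mll1, jund, k4)
    assert res.frame["code"].iloc[0] == 0b101
    assert category_label(0b101) == "M+J-K+"


def test_all_empty_partners_single_category():
    menin = _ps([("chr1", i * 1000, i * 1000 + 100) for i in range(10)])
    empty = _ps([])
    res = classify_peaks(menin, empty, empty, empty)
    assert res.counts[0] == 10
    assert res.percentages[0] == pytest.approx(100.0)


def test_counts_sum_to_total_and_percentages_to_100(landscape):
    d = landscape["data"]
    res = classify_peaks(d.peak_sets["menin"], d.peak_sets["mll1"],
                         d.peak_sets["jund"], d.peak_sets["k4me3"])
    assert sum(res.counts.values()) == len(d.peak_sets["menin"])
    assert sum(res.percentages.values()) == pytest.approx(100.0)


def _brute_force_codes(menin, mll1, jund, k4me3):
    def overlaps(iv, other):
        return any(
            o.chrom == iv.chrom and o.start < iv.end and o.end > iv.start
            for o in other
        )

    return np.array(
        [
            4 * overlaps(iv, mll1) + 2 * overlaps(iv, jund) + overlaps(iv, k4me3)
            for iv in menin
        ]
    )


def test_classification_equals_brute_force_on_random_sets():
    rng = np.random.default_rng(5)

    def random_set(n, label):
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, 50_000))
            ivs.append(GenomicInterval(f"chr{rng.integers(1, 3)}", s,
                                       s + int(rng.integers(50, 800))))
        return PeakSet(ivs, label=label)

    menin = random_set(300, "menin")
    mll1 = random_set(150, "mll1")
    jund = random_set(150, "jund")
    k4 = random_set(150, "k4me3")
    res = classify_peaks(menin, mll1, jund, k4)
    np.testing.assert_array_equal(
        res.frame["code"].to_numpy(), _brute_force_codes(menin, mll1, jund, k4)
    )


def test_classification_invariant_to_input_order(landscape):
    d = landscape["data"]
    menin = d.peak_sets["menin"]
    shuffled = PeakSet(list(reversed(menin.intervals)), label="menin")
    a = classify_peaks(menin, d.peak_sets["mll1"], d.peak_sets["jund"],
                       d.peak_sets["k4me3"])
    b = classify_peaks(shuffled, d.peak_sets["mll1"], d.peak_sets["jund"],
                       d.peak_sets["k4me3"])
    assert a.counts == b.counts


def test_chromosome_naming_mismatch_is_an_error():
    menin = _ps([("chr1", 0, 100)])
    other = _ps([("1", 0, 100)])
    with pytest.raises(ValueError, match="chromosome"):
        classify_peaks(menin, other, other, other)


def test_planted_categories_recovered_exactly(landscape):
    d = landscape["data"]
    res = classify_peaks(d.peak_sets["menin"], d.peak_sets["mll1"],
                         d.peak_sets["jund"], d.peak_sets["k4me3"])
    np.testing.assert_array_equal(res.frame["code"].to_numpy(), d.truth.codes)
    assert res.frame["cluster"].tolist() == d.truth.clusters


# ------------------------------------------------------------------ motifs

def test_ap1_literal_match():
    genome = {"c": "AATGACTCAGG"}
    ann = motif_annotate(_ps([("c", 0, 11)]), genome)
    assert bool(ann["ap1"].iloc[0]) and ann["assignment"].iloc[0] == "AP-1"


def test_atf_precedence_over_ap1():
    genome = {"c": "GGTGACGTCAGG"}
    ann = motif_annotate(_ps([("c", 0, 12)]), genome)
    assert ann["assignment"].iloc[0] == "ATF"


def test_reverse_strand_ap1_detected():
    # reverse complement of TGAGTCAT contains TGACTCA
    genome = {"c": "TGAGTCAT"}
    ann = motif_annotate(_ps([("c", 0, 8)]), genome)
    assert bool(ann["ap1"].iloc[0])
    assert "TGACTCA" in reverse_complement("TGAGTCAT")


def test_motif_flags_strand_symmetric(landscape):
    d = landscape["data"]
    peaks = d.peak_sets["menin"]
    fwd = motif_annotate(peaks, d.genome)
    # mirror the genome: positions flip, so mirror the peaks as well
    rc_genome = {c: reverse_complement(s) for c, s in d.genome.items()}
    n = {c: len(s) for c, s in d.genome.items()}
    mirrored = PeakSet(
        [GenomicInterval(iv.chrom, n[iv.chrom] - iv.end, n[iv.chrom] - iv.start)
         for iv in peaks]
    )
    rev = motif_annotate(mirrored, rc_genome)
    fwd_sorted = fwd.sort_values(["chrom", "start"])  # already sorted
    rev_map = {
        (r.chrom, n[r.chrom] - r.end, n[r.chrom] - r.start): r.assignment
        for r in rev.itertuples()
    }
    for r in fwd_sorted.itertuples():
        assert rev_map[(r.chrom, r.start, r.end)] == r.assignment


def test_peak_outside_genome_bounds_is_an_error():
    with pytest.raises(ValueError, match="outside genome bounds"):
        motif_annotate(_ps([("c", 0, 100)]), {"c": "ACGT"})


def test_planted_motif_truth_recovered(landscape):
    d = landscape["data"]
    ann = motif_annotate(d.peak_sets["menin"], d.genome)
    agreement = np.mean(
        ann["assignment"].to_numpy() == np.array(d.truth.motif_assignment)
    )
    assert agreement >= 0.98   # boundary effects of injection may add rare hits
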