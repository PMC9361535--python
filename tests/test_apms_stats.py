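"""Moderated statistic, permutation FDR, stoichiometry and recovery."""

import numpy as np
import pandas as pd
import pytest

from meninscope.apms.io import SampleDesign
from meninscope.apms.preprocess import filter_groups, log2_and_impute
from meninscope.apms.sam import sam_d_statistic, sam_permutation_test
from meninscope.apms.stoichiometry import (
    ComplexDefinition,
    StoichiometryTable,
    complex_recovery,
    ibaq_stoichiometry,
)
from meninscope.simulate import InteractomeSpec, simulate_interactome


def _design(n=3):
    return SampleDesign(
        pd.DataFrame(
            {
                "sample": [f"GFP_{i+1}" for i in range(n)]
                + [f"control_{i+1}" for i in range(n)],
                "group": ["GFP"] * n + ["control"] * n,
            }
        )
    )


def test_d_statistic_closed_form_example():
    """Groups (1,2,3) vs (4,5,6) with s0=2: d = −3/(0.8165+2)."""
    d = sam_d_statistic(np.array([[1.0, 2, 3]]), np.array([[4.0, 5, 6]]), s0=2.0)
    assert d[0] == pytest.approx(-3.0 / (np.sqrt(2.0 / 3.0) + 2.0), abs=1e-9)
    assert d[0] == pytest.approx(-1.065, abs=1e-3)


def test_d_statistic_matches_direct_arithmetic_rowwise():
    rng = np.random.default_rng(3)
    x = rng.normal(25, 2, (200, 3))
    y = rng.normal(24, 2, (200, 3))
    d = sam_d_statistic(x, y, s0=2.0)
    for i in range(0, 200, 17):
        diff = x[i].mean() - y[i].mean()
        sp = np.sqrt((x[i].var(ddof=1) + y[i].var(ddof=1)) / 2)
        se = sp * np.sqrt(2.0 / 3.0)
        assert d[i] == pytest.approx(diff / (se + 2.0), rel=1e-12)


def test_identical_group_means_never_significant():
    rng = np.random.default_rng(0)
    base = rng.normal(25, 2, 300)
    mat = np.repeat(base[:, None], 6, axis=1) + rng.normal(0, 0.3, (300, 6))
    # one row with exactly identical groups
    mat[0, :3] = mat[0, 3:]
    data = pd.DataFrame(
        mat, columns=[f"GFP_{i+1}" for i in range(3)] + [f"control_{i+1}" for i in range(3)]
    )
    res = sam_permutation_test(data, _design(), seed=1)
    assert res.frame["d"].iloc[0] == 0.0
    assert not res.frame["significant"].iloc[0]


def test_planted_interactors_all_called(interactome):
    table, design = interactome["table"], interactome["design"]
    truth = interactome["truth"]
    filtered = filter_groups(table)
    data = log2_and_impute(filtered, seed=5)
    res = sam_permutation_test(data, design, seed=5)
    id_by_gene = {g: i for i, g in zip(filtered.ids, filtered.gene_names)}
    for gene in truth.interactors:
        assert res.frame.loc[id_by_gene[gene], "significant"], gene


def test_too_few_permutations_is_an_error():
    data = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)),
                        columns=["a", "b", "c", "d"])
    design = SampleDesign(
        pd.DataFrame({"sample": list("abcd"), "group": ["g", "g", "c", "c"]})
    )
    # 2v2 has C(4,2)=6 assignments → fine; missing values must raise instead
    data.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        sam_permutation_test(data, design)


def test_bait_stoichiometry_is_exactly_one(interactome):
    st = ibaq_stoichiometry(interactome["table"], interactome["design"], "MEN1")
    assert st.stoich_by_gene()["MEN1"] == pytest.approx(1.0)


def test_stoichiometry_hand_example():
    """iBAQ_GFP 2e8 in all reps, control mean 5e7, bait adj 1e9 → 0.15."""
    samples = ["GFP_1", "GFP_2", "GFP_3", "control_1", "control_2", "control_3"]
    header = (
        "Majority protein IDs\tGene names\tPeptides\tUnique peptides\t"
        + "\t".join(f"LFQ intensity {s}" for s in samples)
        + "\t" + "\t".join(f"iBAQ {s}" for s in samples) + "\n"
    )
    lfq = "\t".join(["1e8"] * 6)
    bait = f"B\tBAIT\t9\t9\t{lfq}\t" + "\t".join(["1.05e9"] * 3 + ["5e7"] * 3)
    prey = f"P\tPREY\t9\t9\t{lfq}\t" + "\t".join(["2e8"] * 3 + ["5e7"] * 3)
    from meninscope.apms.io import read_protein_groups

    table = read_protein_groups(header + bait + "\n" + prey)
    st = ibaq_stoichiometry(table, _design(), "BAIT")
    assert st.stoich_by_gene()["PREY"] == pytest.approx((2e8 - 5e7) / 1e9)


def test_bait_not_recovered_is_an_error(interactome):
    table = interactome["table"]
    # a background protein has equal iBAQ in both groups → adj ≈ 0 on average,
    # but may fluctuate; use a contaminant-free background gene far down
    with pytest.raises(ValueError, match="not found"):
        ibaq_stoichiometry(table, interactome["design"], "NOSUCH")


def test_planted_stoichiometries_recovered_within_20_percent(interactome):
    st = ibaq_stoichiometry(interactome["table"], interactome["design"], "MEN1")
    s = st.stoich_by_gene()
    for gene, true in interactome["truth"].interactors.items():
        assert float(s[gene]) == pytest.approx(true, rel=0.2), gene


def test_complex_recovery_identity_and_planted_loss():
    wt = StoichiometryTable(
        pd.DataFrame(
            {"gene": ["KMT2A", "WDR5", "JUND"], "adj_ibaq": [1, 1, 1],
             "stoich": [0.5, 1.0, 0.2], "sd": [0, 0, 0]},
            index=["a", "b", "c"],
        ),
        "MEN1",
    )
    cx = ComplexDefinition({"MLL": {"KMT2A", "WDR5"}, "JunD": {"JUND"}})
    identical = complex_recovery(wt, wt, cx)
    assert identical["recovery"].to_numpy() == pytest.approx([1.0, 1.0])

    mut = StoichiometryTable(
        pd.DataFrame(
            {"gene": ["KMT2A", "WDR5", "JUND"], "adj_ibaq": [1, 1, 1],
             "stoich": [0.1, 0.2, 0.16], "sd": [0, 0, 0]},
            index=["a", "b", "c"],
        ),
        "MEN1",
    )
    rec = complex_recovery(mut, wt, cx)
    assert rec.loc["MLL", "recovery"] == pytest.approx(0.2)
    assert rec.loc["JunD", "recovery"] == pytest.approx(0.8)

    # members absent from the mutant count as zero
    mut0 = StoichiometryTable(
        pd.DataFrame({"gene": ["JUND"], "adj_ibaq": [1], "stoich": [0.2],
                      "sd": [0]}, index=["c"]),
        "MEN1",
    )
    rec0 = complex_recovery(mut0, wt, cx)
    assert rec0.loc["MLL", "recovery"] == 0.0

    with pytest.raises(ValueError, match="no members"):
        complex_recovery(wt, mut0, ComplexDefinition({"X": {"ABSENT"}}))


def test_simulated_complex_recovery_matches_planted_fractions():
    """MLL-set members at 20% of WT and JunD-set at 80% are recovered."""
    mll = {"KMT2A": 0.4, "WDR5": 1.0, "ASH2L": 0.6}
    jun = {"JUND": 0.2, "ATF7": 0.1}
    wt_spec = InteractomeSpec(interactors={**mll, **jun})
    mut_spec = InteractomeSpec(
        interactors={**{g: 0.2 * s for g, s in mll.items()},
                     **{g: 0.8 * s for g, s in jun.items()}}
    )
    t_wt, d_wt, _ = simulate_interactome(wt_spec, seed=21)
    t_mut, d_mut, _ = simulate_interactome(mut_spec, seed=22)
    st_wt = ibaq_stoichiometry(t_wt, d_wt, "MEN1")
    st_mut = ibaq_stoichiometry(t_mut, d_mut, "MEN1")
    cx = ComplexDefinition({"MLL": set(mll), "JunD": set(jun)})
    rec = complex_recovery(st_mut, st_wt, cx)
    assert rec.loc["MLL", "recovery"] == pytest.approx(0.2, rel=0.25)
    assert rec.loc["JunD", "recovery"] == pytest.approx(0.8, rel=0.25)
    assert rec.loc["MLL", "recovery"] < rec.loc["JunD", "recovery"]
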