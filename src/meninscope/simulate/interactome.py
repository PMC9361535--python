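"""Synthetic replicate pull-down tables with planted interactors.

Emulates the statistical structure of a GFP-trap versus control-beads
experiment quantified at the protein-group level: log-normal intensities,
replicate noise on the log2 scale, enrichment of the bait and its planted
interactors in the pull-down samples only, iBAQ proportional to true
stoichiometry × bait abundance, missing-not-at-random censoring of
low-intensity values, and a sprinkling of flagged contaminant/decoy rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ..apms.io import ProteinGroupTable, SampleDesign

__all__ = ["InteractomeSpec", "InteractomeTruth", "simulate_interactome"]


@dataclass
class InteractomeSpec:
    n_proteins: int = 500             # background protein groups
    n_replicates: int = 3
    bait: str = "MEN1"
    #: gene → true stoichiometry relative to the bait (bait itself is 1)
    interactors: Dict[str, float] = field(default_factory=dict)
    enrichment_log2: float = 6.0      # planted LFQ enrichment, log2 units
    lfq_noise_sd: float = 0.3         # within-group replicate SD, log2 units
    ibaq_noise_cv: float = 0.1        # multiplicative iBAQ noise
    background_mean_log2: float = 25.0
    background_sd_log2: float = 2.0
    bait_log2: float = 30.0
    bait_ibaq: float = 1e9
    mnar_midpoint_log2: float = 21.5  # logistic censoring midpoint
    mnar_scale_log2: float = 0.8
    contaminant_fraction: float = 0.02
    decoy_fraction: float = 0.02


@dataclass
class InteractomeTruth:
    bait: str
    interactors: Dict[str, float]
    enrichment_log2: float


def simulate_interactome(
    spec: InteractomeSpec, seed: int = 0
) -> Tuple[ProteinGroupTable, SampleDesign, InteractomeTruth]:
    """Generate one experiment; deterministic for a fixed seed."""
    if spec.bait in spec.interactors and spec.interactors[spec.bait] != 1.0:
        raise ValueError("bait stoichiometry must be 1")
    if spec.n_replicates < 2:
        raise ValueError("need ≥2 replicates")
    rng = np.random.default_rng(seed)
    nrep = spec.n_replicates

    pull_samples = [f"GFP_{i + 1}" for i in range(nrep)]
    ctrl_samples = [f"control_{i + 1}" for i in range(nrep)]
    samples = pull_samples + ctrl_samples

    genes: List[str] = [spec.bait]
    stoichs = [1.0]
    for g, s in spec.interactors.items():
        if g == spec.bait:
            continue
        genes.append(g)
        stoichs.append(float(s))
    n_planted = len(genes)
    genes += [f"BG{i:04d}" for i in range(spec.n_proteins)]

    n_total = len(genes)
    lfq = np.zeros((n_total, 2 * nrep))
    ibaq = np.zeros((n_total, 2 * nrep))

    # planted rows: enriched in the pull-down, iBAQ ∝ stoichiometry × bait
    for r, (gene, st) in enumerate(zip(genes[:n_planted], stoichs)):
        gfp_mean = spec.bait_log2 + np.log2(max(st, 1e-12))
        ctrl_mean = gfp_mean - spec.enrichment_log2
        lfq[r, :nrep] = gfp_mean + rng.normal(0, spec.lfq_noise_sd, nrep)
        lfq[r, nrep:] = ctrl_mean + rng.normal(0, spec.lfq_noise_sd, nrep)
        true_ibaq = spec.bait_ibaq * st
        ibaq[r, :nrep] = true_ibaq * (
            1.0 + rng.normal(0, spec.ibaq_noise_cv, nrep)
        )
        ibaq[r, nrep:] = (true_ibaq / 2 ** spec.enrichment_log2) * (
            1.0 + rng.normal(0, spec.ibaq_noise_cv, nrep)
        )

    # background rows: equal means in both groups
    base = rng.normal(spec.background_mean_log2, spec.background_sd_log2,
                      n_total - n_planted)
    for k in range(n_total - n_planted):
        r = n_planted + k
        lfq[r] = base[k] + rng.normal(0, spec.lfq_noise_sd, 2 * nrep)
        ibaq_base = 2.0 ** (base[k] - 4.0)
        ibaq[r] = ibaq_base * (1.0 + rng.normal(0, spec.ibaq_noise_cv, 2 * nrep))

    lfq_linear = 2.0 ** lfq
    ibaq = np.clip(ibaq, 1.0, None)

    # MNAR censoring: logistic in log2 intensity (planted rows in the
    # pull-down are bright enough to be essentially never censored)
    p_missing = 1.0 / (1.0 + np.exp(
        (lfq - spec.mnar_midpoint_log2) / spec.mnar_scale_log2
    ))
    censored = rng.random(lfq.shape) < p_missing
    lfq_linear[censored] = 0.0
    ibaq[censored] = 0.0

    # flagged rows never carry signal of interest
    n_cont = int(round(spec.contaminant_fraction * spec.n_proteins))
    n_decoy = int(round(spec.decoy_fraction * spec.n_proteins))
    contaminant = np.zeros(n_total, bool)
    reverse = np.zeros(n_total, bool)
    bg_rows = np.arange(n_planted, n_total)
    flagged = rng.choice(bg_rows, size=min(n_cont + n_decoy, len(bg_rows)),
                         replace=False)
    contaminant[flagged[:n_cont]] = True
    reverse[flagged[n_cont:]] = True

    peptides = rng.integers(2, 40, n_total)
    unique_peptides = np.maximum(1, (peptides * 0.7).astype(int))

    df = pd.DataFrame({"gene": genes})
    table = ProteinGroupTable(
        ids=pd.Index([f"P{i:05d}|{g}" for i, g in enumerate(genes)]),
        gene_names=pd.Series(genes),
        peptides=pd.Series(peptides),
        unique_peptides=pd.Series(unique_peptides),
        lfq=pd.DataFrame(lfq_linear, columns=samples).where(
            pd.DataFrame(lfq_linear, columns=samples) > 0
        ),
        ibaq=pd.DataFrame(ibaq, columns=samples).where(
            pd.DataFrame(ibaq, columns=samples) > 0
        ),
        contaminant=pd.Series(contaminant),
        reverse=pd.Series(reverse),
        only_by_site=pd.Series(np.zeros(n_total, bool)),
    )
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample": samples,
                "group": ["GFP"] * nrep + ["control"] * nrep,
                "replicate": list(range(1, nrep + 1)) * 2,
                "compartment": ["nuclear"] * (2 * nrep),
            }
        )
    )
    truth = InteractomeTruth(
        bait=spec.bait,
        interactors={g: s for g, s in zip(genes[:n_planted], stoichs)},
        enrichment_log2=spec.enrichment_log2,
    )
    return table, design, truth
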