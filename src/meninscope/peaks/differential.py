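"""Mutant-versus-wild-type peak retention.

A peak is *retained* ("unaffected") when the coverage fold change
WT/mutant is ≤ 4 **or** the p-value of the rate comparison is ≥ 0.001 —
i.e. it is called *lost* only when the drop is both large and significant.
Fold change is directional (loss-focused), computed with a pseudocount,
and the p-value comes from a two-sided Poisson rate comparison of the
rounded normalized counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DifferentialPeakResult", "differential_retention"]


@dataclass
class DifferentialPeakResult:
    frame: pd.DataFrame               # wt, mut, fold_change, p, status
    fc_cut: float
    p_cut: float

    @property
    def retained_percent(self) -> float:
        return 100.0 * float((self.frame["status"] == "retained").mean())

    def per_cluster_retained(self) -> pd.Series:
        if "cluster" not in self.frame.columns:
            raise ValueError("no cluster column attached")
        return (
            self.frame.groupby("cluster")["status"]
            .apply(lambda s: 100.0 * (s == "retained").mean())
        )

    def summary(self) -> pd.DataFrame:
        return self.frame


def _poisson_two_sided_p(k_wt: int, k_mut: int) -> float:
    """Two-sided p for equal Poisson rates via the conditional binomial
    (exact) test: given the total, counts split Binomial(n, 1/2)."""
    n = k_wt + k_mut
    if n == 0:
        return 1.0
    return float(stats.binomtest(k_wt, n, 0.5).pvalue)


def differential_retention(
    wt_cov: np.ndarray,
    mut_cov: np.ndarray,
    pseudocount: float = 1.0,
    fc_cut: float = 4.0,
    p_cut: float = 0.001,
    clusters: Optional[Sequence[str]] = None,
) -> DifferentialPeakResult:
    """Per-peak retained/lost calls from normalized coverage values."""
    wt = np.asarray(wt_cov, float)
    mut = np.asarray(mut_cov, float)
    if wt.shape != mut.shape:
        raise ValueError(f"length mismatch: {wt.shape} vs {mut.shape}")
    if fc_cut <= 1.0:
        raise ValueError("fc_cut must be > 1")

    fc = (wt + pseudocount) / (mut + pseudocount)
    p = np.array(
        [
            _poisson_two_sided_p(int(round(w)), int(round(m)))
            for w, m in zip(wt, mut)
        ]
    )
    lost = (fc > fc_cut) & (p < p_cut)
    frame = pd.DataFrame(
        {
            "wt": wt,
            "mut": mut,
            "fold_change": fc,
            "p": p,
            "status": np.where(lost, "lost", "retained"),
        }
    )
    if clusters is not None:
        frame["cluster"] = list(clusters)
    return DifferentialPeakResult(frame=frame, fc_cut=fc_cut, p_cut=p_cut)
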