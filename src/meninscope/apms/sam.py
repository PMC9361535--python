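"""Moderated two-sample test with permutation-estimated FDR.

The statistic is the classic SAM construction: per protein,

    d = (mean_pulldown − mean_control) / (se + s0)

with ``se`` the pooled (Student) two-sample standard error and ``s0`` a
constant fudge factor damping low-variance proteins (default 2, on the
log2 scale).  Significance is a global two-sided cutoff on |d|: group
labels are permuted (exhaustively when the number of distinct label
assignments is ≤ ``n_perm``, otherwise ``n_perm`` seeded random draws),
and the smallest cutoff whose estimated FDR — median permuted positive
count over observed positive count — stays at or below the target is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleDesign

__all__ = ["DifferentialResult", "sam_d_statistic", "sam_permutation_test"]


@dataclass
class DifferentialResult:
    """Per-protein enrichment calls for one two-group comparison."""

    frame: pd.DataFrame               # delta, d, p, significant per protein
    d_cutoff: float
    fdr: float
    s0: float
    n_permutations: int
    seed: Optional[int]

    def significant_ids(self) -> List[str]:
        return list(self.frame.index[self.frame["significant"]])

    def summary(self) -> pd.DataFrame:
        out = self.frame.sort_values("d", ascending=False)
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n = int(self.frame["significant"].sum())
        return (
            f"<DifferentialResult: {len(self.frame)} proteins, {n} significant "
            f"at FDR {self.fdr} (s0={self.s0}, |d| ≥ {self.d_cutoff:.3g})>"
        )


def sam_d_statistic(
    x: np.ndarray, y: np.ndarray, s0: float = 2.0
) -> np.ndarray:
    """d = (mean(x) − mean(y)) / (pooled SE + s0), row-wise.

    ``x``/``y`` are proteins × replicates arrays.
    """
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    n1, n2 = x.shape[1], y.shape[1]
    diff = x.mean(axis=1) - y.mean(axis=1)
    sp2 = ((n1 - 1) * x.var(axis=1, ddof=1) + (n2 - 1) * y.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return diff / (se + s0)


def _label_assignments(
    n_samples: int, n_group1: int, n_perm: int, rng: np.random.Generator
) -> List[Tuple[int, ...]]:
    all_combos = list(combinations(range(n_samples), n_group1))
    if len(all_combos) < 2:
        raise ValueError("fewer than 2 distinct permutations possible")
    if len(all_combos) <= n_perm:
        return all_combos
    picks = rng.choice(len(all_combos), size=n_perm, replace=False)
    return [all_combos[i] for i in picks]


def sam_permutation_test(
    data: pd.DataFrame,
    design: SampleDesign,
    s0: float = 2.0,
    fdr: float = 0.01,
    n_perm: int = 250,
    seed: Optional[int] = 0,
    group_order: Optional[Sequence[str]] = None,
) -> DifferentialResult:
    """Call enriched proteins in ``data`` (proteins × samples, log2, complete).

    The contrast is group1 − group2 of ``group_order`` (default: design
    order, i.e. pull-down minus control when the design lists the pull-down
    group first).
    """
    if data.isna().any().any():
        raise ValueError("data contains missing values; impute first")
    groups = list(group_order) if group_order is not None else design.groups
    g1 = design.samples(groups[0])
    g2 = design.samples(groups[1])
    missing = [s for s in g1 + g2 if s not in data.columns]
    if missing:
        raise ValueError(f"samples not in data: {missing}")

    rng = np.random.default_rng(seed)
    mat = data[g1 + g2].to_numpy(float)
    n1 = len(g1)

    d_obs = sam_d_statistic(mat[:, :n1], mat[:, n1:], s0)

    # raw two-tailed p from the unmoderated t statistic
    t_res = stats.ttest_ind(mat[:, :n1], mat[:, n1:], axis=1)
    p_raw = np.asarray(t_res.pvalue)

    assignments = _label_assignments(mat.shape[1], n1, n_perm, rng)
    abs_obs = np.abs(d_obs)
    perm_d = np.empty((len(assignments), mat.shape[0]))
    for k, combo in enumerate(assignments):
        idx1 = list(combo)
        idx2 = [i for i in range(mat.shape[1]) if i not in combo]
        perm_d[k] = sam_d_statistic(mat[:, idx1], mat[:, idx2], s0)
    abs_perm = np.abs(perm_d)

    # smallest |d| cutoff with estimated FDR ≤ target
    candidates = np.sort(np.unique(abs_obs))
    cutoff = np.inf
    for cut in candidates:
        obs_pos = int((abs_obs >= cut).sum())
        if obs_pos == 0:
            continue
        perm_pos = (abs_perm >= cut).sum(axis=1)
        est = float(np.median(perm_pos)) / obs_pos
        if est <= fdr:
            cutoff = float(cut)
            break

    significant = abs_obs >= cutoff
    delta = mat[:, :n1].mean(axis=1) - mat[:, n1:].mean(axis=1)
    frame = pd.DataFrame(
        {
            "delta": delta,
            "d": d_obs,
            "p": p_raw,
            "significant": significant,
        },
        index=data.index,
    )
    return DifferentialResult(
        frame=frame,
        d_cutoff=cutoff,
        fdr=fdr,
        s0=s0,
        n_permutations=len(assignments),
        seed=seed,
    )
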