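"""Row filtering and log2/imputation preprocessing.

Filtering drops contaminants, reverse decoys and identified-by-site groups,
groups without unique peptides, and groups below the peptide-count floor.

Imputation emulates the downshifted-normal strategy used for
missing-not-at-random pull-down data: per sample column, missing log2
values are drawn from ``Normal(μ − shift·σ, (width·σ)²)`` where μ and σ are
that column's observed mean and standard deviation (defaults
width = 0.3, shift = 1.8).  Observed values are left bit-identical.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .io import ProteinGroupTable

__all__ = ["filter_groups", "log2_and_impute"]


def filter_groups(
    table: ProteinGroupTable,
    min_peptides: int = 2,
    require_unique: bool = True,
) -> ProteinGroupTable:
    """Apply the three standard quality filters; may return an empty table."""
    mask = ~(table.contaminant | table.reverse | table.only_by_site)
    mask &= table.peptides >= min_peptides
    if require_unique:
        mask &= table.unique_peptides > 0
    out = table.subset(mask.values)
    if len(table) and not len(out):
        warnings.warn("all protein groups removed by filtering", stacklevel=2)
    return out


def log2_and_impute(
    table: ProteinGroupTable,
    width: float = 0.3,
    shift: float = 1.8,
    seed: Optional[int] = 0,
) -> pd.DataFrame:
    """log2-transform LFQ intensities and impute missing values.

    Returns a proteins × samples frame (index = protein ids) with no
    missing entries; reproducible for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    log2 = np.log2(table.lfq.astype(float))
    log2.index = table.ids
    out = log2.copy()
    for col in out.columns:
        observed = out[col].dropna()
        if len(observed) < 2:
            raise ValueError(
                f"sample {col!r} has {len(observed)} observed values; "
                "imputation distribution undefined"
            )
        mu, sigma = float(observed.mean()), float(observed.std(ddof=1))
        miss = out[col].isna()
        if miss.any():
            out.loc[miss, col] = rng.normal(
                mu - shift * sigma, width * sigma, size=int(miss.sum())
            )
    return out
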