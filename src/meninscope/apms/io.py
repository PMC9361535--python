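"""Protein-group table and sample-design input.

The table dialect is the MaxQuant ``proteinGroups.txt`` tab-separated
layout: one row per protein group, ``LFQ intensity <sample>`` and
``iBAQ <sample>`` intensity blocks on linear scale, and "+"-marked flag
columns for contaminants, reverse decoys and identified-by-site groups.
Zero intensities mean "not quantified" and are stored as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ProteinGroupTable", "SampleDesign", "read_protein_groups", "read_design"]

_REQUIRED = ["Majority protein IDs", "Peptides", "Unique peptides"]


@dataclass
class ProteinGroupTable:
    """Per-protein-group quantification across samples.

    ``lfq`` and ``ibaq`` are proteins × samples frames (linear intensities,
    ``NaN`` = missing) sharing the same sample columns and row index.
    """

    ids: pd.Index                     # majority protein ids (unique)
    gene_names: pd.Series
    peptides: pd.Series
    unique_peptides: pd.Series
    lfq: pd.DataFrame
    ibaq: pd.DataFrame
    contaminant: pd.Series
    reverse: pd.Series
    only_by_site: pd.Series

    def __post_init__(self) -> None:
        if self.ids.has_duplicates:
            raise ValueError("protein group ids are not unique")
        if list(self.lfq.columns) != list(self.ibaq.columns):
            raise ValueError("LFQ and iBAQ sample columns differ")

    @property
    def samples(self) -> List[str]:
        return list(self.lfq.columns)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, mask: pd.Series) -> "ProteinGroupTable":
        return ProteinGroupTable(
            ids=self.ids[mask],
            gene_names=self.gene_names[mask],
            peptides=self.peptides[mask],
            unique_peptides=self.unique_peptides[mask],
            lfq=self.lfq[mask],
            ibaq=self.ibaq[mask],
            contaminant=self.contaminant[mask],
            reverse=self.reverse[mask],
            only_by_site=self.only_by_site[mask],
        )

    def to_tsv(self) -> str:
        df = pd.DataFrame(
            {
                "Majority protein IDs": self.ids,
                "Gene names": self.gene_names.values,
                "Peptides": self.peptides.values,
                "Unique peptides": self.unique_peptides.values,
            }
        )
        for s in self.samples:
            df[f"LFQ intensity {s}"] = self.lfq[s].fillna(0).values
        for s in self.samples:
            df[f"iBAQ {s}"] = self.ibaq[s].fillna(0).values
        df["Potential contaminant"] = np.where(self.contaminant.values, "+", "")
        df["Reverse"] = np.where(self.reverse.values, "+", "")
        df["Only identified by site"] = np.where(self.only_by_site.values, "+", "")
        return df.to_csv(sep="\t", index=False)


def _flag(df: pd.DataFrame, col: str) -> pd.Series:
    if col in df.columns:
        return df[col].fillna("").astype(str).str.strip().eq("+")
    return pd.Series(False, index=df.index)


def read_protein_groups(tsv_text: str) -> ProteinGroupTable:
    """Parse protein-group TSV text; raises listing any missing columns."""
    df = pd.read_csv(StringIO(tsv_text), sep="\t", dtype=str)
    lfq_cols = [c for c in df.columns if c.startswith("LFQ intensity ")]
    ibaq_cols = [
        c for c in df.columns
        if c.startswith("iBAQ ") and c not in ("iBAQ peptides",)
    ]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if not lfq_cols:
        missing.append("LFQ intensity <sample>")
    if not ibaq_cols:
        missing.append("iBAQ <sample>")
    if missing:
        raise ValueError(f"protein-group table missing columns: {missing}")

    samples_lfq = [c[len("LFQ intensity "):] for c in lfq_cols]
    samples_ibaq = [c[len("iBAQ "):] for c in ibaq_cols]
    if set(samples_lfq) != set(samples_ibaq):
        raise ValueError(
            f"LFQ samples {sorted(samples_lfq)} != iBAQ samples {sorted(samples_ibaq)}"
        )
    samples = samples_lfq

    def intensity_block(prefix: str) -> pd.DataFrame:
        block = pd.DataFrame(index=df.index)
        for s in samples:
            vals = pd.to_numeric(df[f"{prefix}{s}"], errors="coerce")
            block[s] = vals.where(vals > 0)  # zero or unparsable → missing
        return block

    gene = df.get("Gene names", pd.Series("", index=df.index)).fillna("")
    return ProteinGroupTable(
        ids=pd.Index(df["Majority protein IDs"].astype(str)),
        gene_names=gene.astype(str),
        peptides=pd.to_numeric(df["Peptides"], errors="coerce").fillna(0).astype(int),
        unique_peptides=pd.to_numeric(df["Unique peptides"], errors="coerce")
        .fillna(0)
        .astype(int),
        lfq=intensity_block("LFQ intensity "),
        ibaq=intensity_block("iBAQ "),
        contaminant=_flag(df, "Potential contaminant"),
        reverse=_flag(df, "Reverse"),
        only_by_site=_flag(df, "Only identified by site"),
    )


@dataclass
class SampleDesign:
    """Sample → group assignment for one two-group pull-down comparison."""

    frame: pd.DataFrame               # columns: sample, group, replicate, compartment

    def __post_init__(self) -> None:
        required = {"sample", "group"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"design needs columns {sorted(required)}")
        groups = self.frame["group"].unique()
        if len(groups) != 2:
            raise ValueError(f"need exactly two groups, got {list(groups)}")
        counts = self.frame.groupby("group")["sample"].count()
        if (counts < 2).any():
            raise ValueError("each group needs ≥2 samples")
        if self.frame["sample"].duplicated().any():
            raise ValueError("duplicate sample names in design")

    @property
    def groups(self) -> List[str]:
        return list(pd.unique(self.frame["group"]))

    def samples(self, group: str) -> List[str]:
        return list(self.frame.loc[self.frame["group"] == group, "sample"])


def read_design(tsv_text: str) -> SampleDesign:
    return SampleDesign(pd.read_csv(StringIO(tsv_text), sep="\t", dtype=str))
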