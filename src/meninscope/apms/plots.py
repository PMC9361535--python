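"""Basic volcano and stoichiometry figures."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sam import DifferentialResult
from .stoichiometry import StoichiometryTable

__all__ = ["volcano_plot", "stoichiometry_plot"]


def volcano_plot(result: DifferentialResult, path: str | Path,
                 title: str = "") -> None:
    """Δlog2 vs −log10 p, significant proteins highlighted."""
    frame = result.frame
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = frame["significant"]
    ax.scatter(frame.loc[~sig, "delta"], -np.log10(frame.loc[~sig, "p"]),
               s=6, c="lightgrey", label="n.s.")
    ax.scatter(frame.loc[sig, "delta"], -np.log10(frame.loc[sig, "p"]),
               s=10, c="crimson", label=f"FDR {result.fdr}, s0 {result.s0}")
    ax.set_xlabel("log2 (pull-down / control)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def stoichiometry_plot(table: StoichiometryTable, path: str | Path,
                       top: int = 25, title: str = "") -> None:
    """Bait-normalized stoichiometries of the most abundant interactors,
    whiskers showing replicate SD."""
    frame = table.frame.sort_values("stoich", ascending=False).head(top)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(frame)), 4))
    ax.bar(frame["gene"], frame["stoich"], yerr=frame["sd"].fillna(0),
           color="steelblue", capsize=2)
    ax.set_ylabel(f"stoichiometry relative to {table.bait_id}")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
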