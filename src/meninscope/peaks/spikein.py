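"""Spike-in normalization of control tracks.

With exogenous spike-in chromatin added at a constant ratio to every
sample, the spike-per-target read ratio measures inverse recovery; the
control/IgG track is rescaled by

    f = (spike_exp / target_exp) / (spike_ctrl / target_ctrl)

so control and experiment become comparable (equal spike-per-target ratios
give f = 1).  The factor is dimensionless and linear in the experiment's
spike-in reads.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SpikeInStats", "spike_in_scale"]


@dataclass(frozen=True)
class SpikeInStats:
    sample: str
    target_reads: int                # reads mapped to the target genome
    spike_reads: int                 # reads mapped to the spike-in genome
    total_reads: int

    def __post_init__(self) -> None:
        if min(self.target_reads, self.spike_reads, self.total_reads) < 0:
            raise ValueError("read counts must be ≥ 0")
        if self.spike_reads + self.target_reads > self.total_reads:
            raise ValueError("spike + target reads exceed total reads")


def spike_in_scale(control: SpikeInStats, experiment: SpikeInStats) -> float:
    """Normalization factor for the control track (see module docstring)."""
    if control.spike_reads == 0 or experiment.spike_reads == 0:
        raise ValueError("spike-in absent")
    if control.target_reads == 0 or experiment.target_reads == 0:
        raise ValueError("no target-genome reads")
    ratio_ctrl = control.spike_reads / control.target_reads
    ratio_exp = experiment.spike_reads / experiment.target_reads
    return ratio_exp / ratio_ctrl
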