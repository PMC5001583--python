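"""Targeted bisulfite summaries and conversion-efficiency QC.

Works on per-CpG methylated/unmethylated read counts (CpG dyads collapsed to
the forward-strand C).  Alongside per-amplicon summaries it estimates
bisulfite conversion efficiency from two spike-in controls: a fully
unmethylated control (its converted fraction estimates the conversion rate)
and a fully methylated control (its converted fraction is a proxy for
over-conversion).  Conversion below ``QC_CONVERSION_MIN`` raises a QC flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GenomicInterval, MethCall

__all__ = [
    "AmpliconSummary",
    "QC_CONVERSION_MIN",
    "methylation_percent",
    "summarize_amplicon",
    "conversion_efficiency",
    "average_replicates",
]

QC_CONVERSION_MIN = 0.98


@dataclass
class AmpliconSummary:
    """Per-CpG and mean methylation for one bisulfite amplicon."""

    amplicon: GenomicInterval
    per_cpg_percent: dict[int, float]
    mean_percent: float
    n_cpgs: int
    total_depth: int

    def __post_init__(self):
        if self.n_cpgs != len(self.per_cpg_percent):
            raise ValueError("n_cpgs must equal the number of per-CpG entries")
        for pos, pct in self.per_cpg_percent.items():
            if not (0.0 <= pct <= 100.0):
                raise ValueError(f"percent {pct} at {pos} outside [0, 100]")


def methylation_percent(call: MethCall) -> float:
    """100 * meth / (meth + unmeth); undefined at zero depth."""
    if call.depth == 0:
        raise ValueError(
            f"zero depth at {call.contig}:{call.position}: percent undefined"
        )
    return 100.0 * call.meth_count / call.depth


def summarize_amplicon(
    amplicon: GenomicInterval, calls: Sequence[MethCall]
) -> AmpliconSummary:
    """Summarize the calls falling inside one amplicon.

    Zero-depth CpGs are excluded with a warning; the amplicon mean is the
    unweighted mean of per-CpG percentages.
    """
    per_cpg: dict[int, float] = {}
    total_depth = 0
    for call in calls:
        if call.contig != amplicon.contig or not amplicon.contains_position(
            call.position
        ):
            continue
        if call.depth == 0:
            warnings.warn(
                f"CpG {call.contig}:{call.position} has zero depth; excluded",
                stacklevel=2,
            )
            continue
        per_cpg[call.position] = methylation_percent(call)
        total_depth += call.depth
    mean = float(np.mean(list(per_cpg.values()))) if per_cpg else float("nan")
    return AmpliconSummary(
        amplicon=amplicon,
        per_cpg_percent=per_cpg,
        mean_percent=mean,
        n_cpgs=len(per_cpg),
        total_depth=total_depth,
    )


def conversion_efficiency(
    unmeth_spikein: Sequence[MethCall], meth_spikein: Sequence[MethCall]
) -> dict:
    """Pooled conversion estimates from the two spike-in controls.

    ``conversion`` is the fraction of unmethylated-control cytosines read as
    converted (unmethylated); ``overconversion_proxy`` is the converted
    fraction of the methylated control.  ``qc_pass`` is False when
    conversion falls below :data:`QC_CONVERSION_MIN`.
    """
    if not unmeth_spikein or not meth_spikein:
        raise ValueError("both spike-in sets must be non-empty")
    um_unmeth = sum(c.unmeth_count for c in unmeth_spikein)
    um_total = sum(c.depth for c in unmeth_spikein)
    m_unmeth = sum(c.unmeth_count for c in meth_spikein)
    m_total = sum(c.depth for c in meth_spikein)
    if um_total == 0 or m_total == 0:
        raise ValueError("spike-in sets must have positive total depth")
    conversion = um_unmeth / um_total
    overconversion = m_unmeth / m_total
    return {
        "conversion": conversion,
        "overconversion_proxy": overconversion,
        "qc_pass": conversion >= QC_CONVERSION_MIN,
    }


def average_replicates(rep_summaries: Sequence[AmpliconSummary]) -> AmpliconSummary:
    """Unweighted per-CpG mean of replicate summaries of one amplicon."""
    if not rep_summaries:
        raise ValueError("need at least one replicate summary")
    first = rep_summaries[0]
    keys = set(first.per_cpg_percent)
    for rep in rep_summaries[1:]:
        if rep.amplicon != first.amplicon:
            raise ValueError("replicate summaries describe different amplicons")
        if set(rep.per_cpg_percent) != keys:
            raise ValueError("replicate summaries differ in CpG positions")
    per_cpg = {
        pos: float(np.mean([rep.per_cpg_percent[pos] for rep in rep_summaries]))
        for pos in sorted(keys)
    }
    mean = float(np.mean(list(per_cpg.values()))) if per_cpg else float("nan")
    return AmpliconSummary(
        amplicon=first.amplicon,
        per_cpg_percent=per_cpg,
        mean_percent=mean,
        n_cpgs=len(per_cpg),
        total_depth=sum(rep.total_depth for rep in rep_summaries),
    )
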