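"""Shared vs species-specific HMR classification across two host contexts.

The unit of comparison is the union of HMRs called in the two contexts:
overlapping intervals are merged so that partially-overlapping peaks are not
double counted.  Read counts over each union interval are normalized to a
common sequencing depth and the classical 2-fold rule applied: an interval
whose normalized BioCAP signal differs by more than ``fold_threshold``
between contexts is species-specific (hypomethylated only in the enriched
context); everything else is shared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_formats import CoverageTrack, GenomicInterval
from .hmr_detection import Hmr

__all__ = [
    "DifferentialParams",
    "merge_union",
    "normalize_to_common_depth",
    "classify_hmrs",
    "tissue_specificity",
    "replicate_r2",
]

SPECIFIC_LABELS = ("A_specific", "B_specific")


@dataclass
class DifferentialParams:
    #: normalized-count ratio beyond which an HMR is species-specific
    fold_threshold: float = 2.0
    #: added to both counts before the ratio; guards zero-count intervals
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def _as_interval(item) -> GenomicInterval:
    return item.interval if isinstance(item, Hmr) else item


def merge_union(
    hmrs_a: Sequence[Hmr | GenomicInterval],
    hmrs_b: Sequence[Hmr | GenomicInterval],
) -> list[GenomicInterval]:
    """Maximal unions of overlapping intervals from the two sets, sorted."""
    ivs = sorted(
        (_as_interval(x) for x in list(hmrs_a) + list(hmrs_b)),
        key=lambda iv: (iv.contig, iv.start, iv.end),
    )
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].contig == iv.contig and iv.start < out[-1].end:
            last = out[-1]
            out[-1] = GenomicInterval(last.contig, last.start, max(last.end, iv.end))
        else:
            out.append(GenomicInterval(iv.contig, iv.start, iv.end))
    return out


def normalize_to_common_depth(
    count_a: float, total_a: float, count_b: float, total_b: float
) -> tuple[float, float]:
    """Scale context-B counts onto context A's sequencing depth."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    return float(count_a), float(count_b * total_a / total_b)


def classify_hmrs(
    union: Sequence[GenomicInterval],
    cov_a: CoverageTrack,
    cov_b: CoverageTrack,
    params: DifferentialParams | None = None,
) -> list[Hmr]:
    """Label each union interval shared / A_specific / B_specific.

    ``fold`` is the pseudocounted ratio of depth-normalized fragment counts
    (A over B); fold > threshold means hypomethylated specifically in A,
    1/fold > threshold specifically in B.  The summit is the leftmost
    maximum of the summed coverage, so downstream point-overlap annotation
    works on classified intervals too.
    """
    params = params or DifferentialParams()
    out: list[Hmr] = []
    for idx, iv in enumerate(union):
        if iv.length == 0:
            raise ValueError(f"zero-length interval {iv}")
        n_a = cov_a.estimate_fragments(iv.start, iv.end)
        n_b = cov_b.estimate_fragments(iv.start, iv.end)
        n_a, n_b_norm = normalize_to_common_depth(
            n_a, cov_a.total_reads, n_b, cov_b.total_reads
        )
        fold = (n_a + params.pseudocount) / (n_b_norm + params.pseudocount)
        if fold > params.fold_threshold:
            label = "A_specific"
        elif 1.0 / fold > params.fold_threshold:
            label = "B_specific"
        else:
            label = "shared"
        combined = cov_a.values[iv.start : iv.end] + cov_b.values[iv.start : iv.end]
        summit = iv.start + int(np.argmax(combined))
        out.append(
            Hmr(
                interval=GenomicInterval(iv.contig, iv.start, iv.end, name=f"hmr_{idx}"),
                summit=summit,
                p_value=float("nan"),
                reads_by_sample={"A": n_a, "B_normalized": n_b_norm},
                label=label,
                fold=fold,
            )
        )
    return out


def tissue_specificity(
    ss_by_tissue: Mapping[str, Sequence[Hmr]],
) -> dict[str, dict]:
    """Fraction of species-specific HMRs unique to a single tissue.

    An ssHMR is *unique* when it overlaps (>= 1 bp) no same-label ssHMR in
    any other tissue.  Returns, per specific label, pooled and per-tissue
    counts and fractions.
    """
    if len(ss_by_tissue) < 2:
        raise ValueError("tissue_specificity needs >= 2 tissues")
    out: dict[str, dict] = {}
    for label in SPECIFIC_LABELS:
        per_tissue: dict[str, dict] = {}
        n_total = 0
        n_unique = 0
        for tissue, hmrs in ss_by_tissue.items():
            own = [h for h in hmrs if h.label == label]
            others = [
                o.interval
                for t2, hmrs2 in ss_by_tissue.items()
                if t2 != tissue
                for o in hmrs2
                if o.label == label
            ]
            unique = [
                h for h in own if not any(h.interval.overlaps(o) for o in others)
            ]
            per_tissue[tissue] = {
                "n": len(own),
                "n_unique": len(unique),
                "fraction_unique": len(unique) / len(own) if own else float("nan"),
            }
            n_total += len(own)
            n_unique += len(unique)
        out[label] = {
            "n": n_total,
            "n_unique": n_unique,
            "fraction_unique": n_unique / n_total if n_total else float("nan"),
            "by_tissue": per_tissue,
        }
    return out


def replicate_r2(counts_rep1, counts_rep2) -> float:
    """Squared Pearson correlation between two replicate count vectors."""
    x = np.asarray(counts_rep1, dtype=np.float64)
    y = np.asarray(counts_rep2, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("replicate vectors must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
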