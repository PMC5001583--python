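"""Interval-overlap annotation of HMRs.

Covers TSS-proximity partitioning (promoter window = TSS +/- ``tss_window``
bp, both endpoints inclusive), cross-context transcription-factor peak
intersection (stratified by factor: a binding event is context-specific when
no same-factor peak of the other context overlaps it), multi-way Venn-style
overlap summaries, and centered length-ranked signal matrices for
heatmap/metaplot figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import CoverageTrack, GenomicInterval
from .hmr_detection import Hmr

__all__ = [
    "AnnotationParams",
    "TfPeak",
    "classify_tss_proximity",
    "species_specific_peaks",
    "multiway_overlap_summary",
    "aggregate_matrix",
    "fold_change_by_location",
]

#: sentinel used to pad matrix rows that run off the contig edge
MISSING = float("nan")


@dataclass
class AnnotationParams:
    #: half-width of the promoter window on each side of the TSS
    tss_window: int = 500

    def __post_init__(self):
        if self.tss_window < 0:
            raise ValueError("tss_window must be >= 0")


@dataclass(frozen=True)
class TfPeak:
    """A transcription-factor ChIP peak observed in one host context."""

    interval: GenomicInterval
    factor: str
    context: str

    def __post_init__(self):
        if not self.factor:
            raise ValueError("factor name must be non-empty")


def classify_tss_proximity(
    hmrs: Sequence[Hmr],
    tss: Sequence[GenomicInterval],
    params: AnnotationParams | None = None,
) -> tuple[list[Hmr], list[Hmr]]:
    """Partition HMRs into (TSS-associated, distal).

    An HMR is TSS-associated iff it overlaps ``[tss - w, tss + w + 1)`` for
    any TSS — a (2w + 1)-position footprint inclusive of both endpoints.
    Strand does not alter the window.
    """
    params = params or AnnotationParams()
    w = params.tss_window
    windows = [
        GenomicInterval(t.contig, max(0, t.start - w), t.start + w + 1) for t in tss
    ]
    associated: list[Hmr] = []
    distal: list[Hmr] = []
    for hmr in hmrs:
        if any(hmr.interval.overlaps(win) for win in windows):
            associated.append(hmr)
        else:
            distal.append(hmr)
    return associated, distal


def species_specific_peaks(
    peaks_a: Sequence[TfPeak], peaks_b: Sequence[TfPeak]
) -> dict[str, list[TfPeak]]:
    """Split TF peaks into a_specific / b_specific / shared by cross-context
    intersection, comparing only peaks of the same factor.

    ``shared`` pools the shared peaks of both contexts (each context's shared
    peaks keep their own coordinates).
    """

    def _split(own: Sequence[TfPeak], other: Sequence[TfPeak]):
        by_factor: dict[str, list[TfPeak]] = {}
        for p in other:
            by_factor.setdefault(p.factor, []).append(p)
        specific, shared = [], []
        for p in own:
            if any(p.interval.overlaps(q.interval) for q in by_factor.get(p.factor, ())):
                shared.append(p)
            else:
                specific.append(p)
        return specific, shared

    a_specific, a_shared = _split(peaks_a, peaks_b)
    b_specific, b_shared = _split(peaks_b, peaks_a)
    return {
        "a_specific": a_specific,
        "b_specific": b_specific,
        "shared": a_shared + b_shared,
    }


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def multiway_overlap_summary(
    targets: Sequence[Hmr | GenomicInterval],
    feature_sets: Mapping[str, Sequence[GenomicInterval | TfPeak]],
) -> dict:
    """Venn-style membership counts of targets across up to 4 feature sets.

    Returns the count of targets per membership pattern (tuple of booleans in
    feature-set order), the number overlapping at least one set, and that
    number as a percentage of all targets rounded half-up to an integer —
    the convention used when reporting figures like "31% (23/75)".
    """
    if not targets:
        raise ValueError("target list must be non-empty")
    if len(feature_sets) > 4:
        raise ValueError("at most 4 feature sets supported")
    names = list(feature_sets.keys())
    sets = [
        [f.interval if isinstance(f, TfPeak) else f for f in feature_sets[n]]
        for n in names
    ]
    pattern_counts: dict[tuple[bool, ...], int] = {}
    n_any = 0
    for t in targets:
        iv = t.interval if isinstance(t, Hmr) else t
        pattern = tuple(any(iv.overlaps(f) for f in s) for s in sets)
        pattern_counts[pattern] = pattern_counts.get(pattern, 0) + 1
        if any(pattern):
            n_any += 1
    return {
        "set_names": names,
        "pattern_counts": pattern_counts,
        "n_targets": len(targets),
        "n_overlapping": n_any,
        "percent_overlapping": _round_half_up(100.0 * n_any / len(targets)),
    }


def aggregate_matrix(
    intervals: Sequence[Hmr | GenomicInterval],
    coverage: CoverageTrack,
    flank: int,
    bins: int,
) -> tuple[np.ndarray, list[GenomicInterval], np.ndarray]:
    """Signal matrix centered on interval midpoints, ranked by length.

    Row i holds the mean coverage in ``bins`` equal windows spanning
    ``[mid - flank, mid + flank)`` for the i-th interval after sorting by
    length descending (ties broken by start).  Bins that fall outside the
    contig are set to NaN.  Returns ``(matrix, sorted_intervals,
    column_means)`` where column means (NaN-aware) form the metaplot vector.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    ivs = [t.interval if isinstance(t, Hmr) else t for t in intervals]
    order = sorted(range(len(ivs)), key=lambda i: (-ivs[i].length, ivs[i].start))
    ivs = [ivs[i] for i in order]

    L = len(coverage)
    edges = np.rint(np.linspace(-flank, flank, bins + 1)).astype(np.int64)
    matrix = np.full((len(ivs), bins), MISSING)
    for row, iv in enumerate(ivs):
        mid = (iv.start + iv.end) // 2
        for b in range(bins):
            lo, hi = mid + edges[b], mid + edges[b + 1]
            if lo < 0 or hi > L or hi <= lo:
                continue
            matrix[row, b] = float(coverage.values[lo:hi].mean())
    if len(ivs):
        # columns that are NaN in every row (all intervals off-contig) stay NaN
        counts = np.sum(~np.isnan(matrix), axis=0)
        sums = np.nansum(matrix, axis=0)
        column_means = np.where(counts > 0, sums / np.maximum(counts, 1), MISSING)
    else:
        column_means = np.full(bins, MISSING)
    return matrix, ivs, column_means


def fold_change_by_location(
    hmrs: Sequence[Hmr],
    tss_associated: Sequence[Hmr],
) -> dict:
    """Welch's t-test of per-HMR fold change, TSS-associated vs distal.

    Fold changes are taken from each HMR's ``fold`` attribute as the
    magnitude of change ``max(fold, 1/fold)`` so both directions of
    specificity are on a common scale.  Raises when either group has fewer
    than two members or both groups are constant (t undefined).
    """
    assoc_keys = {id(h) for h in tss_associated}
    groups: dict[str, list[float]] = {"tss": [], "distal": []}
    for h in hmrs:
        if h.fold is None:
            raise ValueError(f"HMR {h.interval} has no fold change")
        magnitude = max(h.fold, 1.0 / h.fold)
        groups["tss" if id(h) in assoc_keys else "distal"].append(magnitude)
    x = np.array(groups["tss"])
    y = np.array(groups["distal"])
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need >= 2 HMRs")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate variance: Welch's t undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    return {
        "tss_folds": x,
        "distal_folds": y,
        "t_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }
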