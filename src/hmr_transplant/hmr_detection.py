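"""Hypomethylated-region (HMR) peak calling from BioCAP coverage.

A fully specified, window-based re-statement of the classic treatment-vs-input
Poisson peak caller.  Every sliding window of width ``bandwidth`` is scored:
the observed window fragment count is tested against a local Poisson rate
``lambda_local = max(lambda_BG, lambda_1k, lambda_5k, lambda_10k)`` where the
local rates are estimated from the input control over windows centered on the
same point and scaled to the treatment sequencing depth.  Significant windows
(one-sided Poisson tail p <= threshold) are merged, with gaps up to
``merge_gap`` bridged, to produce peaks.  The mfold candidate filter against
the genome-wide background rate is a pre-filter that prunes windows before
scoring; with a realistically large effective genome size it never removes a
window that would have reached significance against the (larger) local rate.

There is no tag-shift model: BioCAP captures fragments directly, so the
coverage track already represents fragment density and the ChIP-style shift
estimation step does not apply.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import CoverageTrack, GenomicInterval

__all__ = [
    "PeakCallParams",
    "Hmr",
    "RearrangementMap",
    "poisson_tail",
    "call_peaks",
    "intersect_replicates",
    "apply_rearrangement_map",
]


@dataclass
class PeakCallParams:
    """Caller tuning knobs (defaults follow common practice for CxxC-capture
    data: 300 bp bandwidth, p = 1e-5 Poisson cutoff, 1/5/10 kb local-rate
    windows, 4.8e8 bp effective genome)."""

    bandwidth: int = 300
    mfold_low: float = 10.0
    mfold_high: float = 30.0
    pvalue_threshold: float = 1e-5
    effective_genome_size: float = 4.8e8
    local_lambda_windows: tuple[int, ...] = (1000, 5000, 10000)
    merge_gap: int = 100

    def __post_init__(self):
        if not (0.0 < self.pvalue_threshold < 1.0):
            raise ValueError("pvalue_threshold must lie in (0, 1)")
        if not (0 < self.mfold_low < self.mfold_high):
            raise ValueError("need 0 < mfold_low < mfold_high")
        if self.bandwidth < 1:
            raise ValueError("bandwidth must be >= 1")
        if list(self.local_lambda_windows) != sorted(self.local_lambda_windows):
            raise ValueError("local_lambda_windows must be ascending")
        if self.effective_genome_size <= 0:
            raise ValueError("effective_genome_size must be positive")


@dataclass
class Hmr:
    """A called peak: interval, summit, score and per-sample read counts."""

    interval: GenomicInterval
    summit: int
    p_value: float
    reads_by_sample: dict[str, float] = field(default_factory=dict)
    label: str = "unclassified"
    fold: float | None = None

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.start}-{self.interval.end}"
            )


@dataclass
class RearrangementMap:
    """Breakpoints, deletions and duplications of the transplanted contig
    relative to the donor assembly (an input, not inferred here)."""

    breakpoints: list[int] = field(default_factory=list)
    deleted: list[GenomicInterval] = field(default_factory=list)
    duplicated: list[tuple[GenomicInterval, int]] = field(default_factory=list)

    def __post_init__(self):
        for _, copy_number in self.duplicated:
            if int(copy_number) != copy_number or copy_number < 2:
                raise ValueError("copy_number must be an integer >= 2")

    def is_empty(self) -> bool:
        return not (self.breakpoints or self.deleted or self.duplicated)


def poisson_tail(observed: int, lam: float) -> float:
    """Upper-tail probability P(X >= observed) for X ~ Poisson(lam).

    Computed through the regularized incomplete gamma function (stable in
    log space for large counts); ``observed = 0`` returns exactly 1.
    """
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if observed < 0 or int(observed) != observed:
        raise ValueError(f"observed must be a non-negative integer, got {observed}")
    return float(stats.poisson.sf(observed - 1, lam))


def _poisson_tail_vec(observed: np.ndarray, lam: np.ndarray) -> np.ndarray:
    return stats.poisson.sf(observed - 1, lam)


def _window_stats(
    treatment: CoverageTrack,
    control: CoverageTrack,
    params: PeakCallParams,
):
    """Observed counts and local lambda for every window start."""
    bw = params.bandwidth
    t = treatment.values
    c = control.values
    L = t.size
    n_windows = L - bw + 1
    fl_t = treatment.mean_fragment_length
    fl_c = control.mean_fragment_length

    cs_t = np.concatenate(([0.0], np.cumsum(t)))
    cs_c = np.concatenate(([0.0], np.cumsum(c)))
    starts = np.arange(n_windows)
    win_sum_t = cs_t[starts + bw] - cs_t[starts]
    observed = np.floor(win_sum_t / fl_t + 0.5)

    # expected fragments overlapping a bandwidth window, genome-wide rate
    lam_bg = treatment.total_reads * (bw + fl_t) / params.effective_genome_size
    lam_local = np.full(n_windows, lam_bg)
    depth_scale = treatment.total_reads / control.total_reads
    centers = starts + bw // 2
    for w in params.local_lambda_windows:
        lo = np.clip(centers - w // 2, 0, L)
        hi = np.clip(centers + w - w // 2, 0, L)
        span = hi - lo
        frags_c = (cs_c[hi] - cs_c[lo]) / fl_c
        lam_w = frags_c * (bw + fl_c) / (span + fl_c) * depth_scale
        np.maximum(lam_local, lam_w, out=lam_local)
    return starts, observed, lam_local, lam_bg, cs_t, fl_t


def _merge_starts(
    sig_starts: np.ndarray, bw: int, merge_gap: int, L: int
) -> list[tuple[int, int]]:
    """Union of [s, s+bw) for significant starts, bridging gaps <= merge_gap."""
    peaks: list[tuple[int, int]] = []
    for s in sig_starts:
        s = int(s)
        e = min(s + bw, L)
        if peaks and s - peaks[-1][1] <= merge_gap:
            peaks[-1] = (peaks[-1][0], max(peaks[-1][1], e))
        else:
            peaks.append((s, e))
    return peaks


def call_peaks(
    treatment: CoverageTrack,
    control: CoverageTrack,
    params: PeakCallParams | None = None,
    sample_id: str = "treatment",
) -> list[Hmr]:
    """Call enrichment peaks on one contig from treatment vs input coverage.

    Returns peaks sorted by start; each carries its summit (leftmost base of
    maximal treatment coverage), the best window p-value, and the estimated
    number of treatment fragments overlapping the peak under ``sample_id``.
    """
    params = params or PeakCallParams()
    if treatment.contig != control.contig:
        raise ValueError(
            f"contig mismatch: {treatment.contig!r} vs {control.contig!r}"
        )
    if len(treatment) != len(control):
        raise ValueError("treatment and control tracks differ in length")
    if control.total_reads <= 0:
        raise ValueError("control track has zero total reads")
    if treatment.total_reads <= 0:
        warnings.warn("treatment track has zero total reads; no peaks called")
        return []
    if len(treatment) < params.bandwidth:
        return []

    starts, observed, lam_local, lam_bg, cs_t, fl_t = _window_stats(
        treatment, control, params
    )
    candidate = observed >= params.mfold_low * lam_bg
    significant = np.zeros_like(candidate)
    if candidate.any():
        p = _poisson_tail_vec(observed[candidate], lam_local[candidate])
        significant[candidate] = p <= params.pvalue_threshold

    sig_starts = starts[significant]
    if sig_starts.size == 0:
        return []
    # p-values for significant windows only, for per-peak minima
    p_sig = _poisson_tail_vec(observed[significant], lam_local[significant])

    L = len(treatment)
    peaks = _merge_starts(sig_starts, params.bandwidth, params.merge_gap, L)
    out: list[Hmr] = []
    for idx, (s, e) in enumerate(peaks):
        inside = (sig_starts >= s) & (sig_starts < e)
        p_value = float(p_sig[inside].min())
        region = treatment.values[s:e]
        summit = s + int(np.argmax(region))  # argmax -> leftmost maximum
        reads = float((cs_t[e] - cs_t[s]) / fl_t)
        out.append(
            Hmr(
                interval=GenomicInterval(
                    treatment.contig, s, e, name=f"peak_{idx}"
                ),
                summit=summit,
                p_value=p_value,
                reads_by_sample={sample_id: reads},
            )
        )
    return out


def intersect_replicates(
    peaks_rep1: Sequence[Hmr], peaks_rep2: Sequence[Hmr]
) -> list[Hmr]:
    """Peaks of replicate 1 with >= 1 bp overlap in replicate 2.

    Replicate-1 coordinates are retained and input order preserved — the
    reproducibility filter that keeps only peaks seen in both biological
    replicates.
    """
    if not peaks_rep1 or not peaks_rep2:
        return []
    rep2 = sorted((h.interval.start, h.interval.end) for h in peaks_rep2)
    starts2 = np.array([s for s, _ in rep2])
    ends2 = np.array([e for _, e in rep2])
    out = []
    for hmr in peaks_rep1:
        i = np.searchsorted(starts2, hmr.interval.end)
        if np.any(ends2[:i] > hmr.interval.start):
            out.append(hmr)
    return out


def apply_rearrangement_map(
    hmrs: Sequence[Hmr], rearrangement_map: RearrangementMap
) -> list[Hmr]:
    """Drop HMRs touching breakpoints or deleted regions; divide read counts
    by copy number inside duplicated regions (fractional counts allowed)."""
    out: list[Hmr] = []
    for hmr in hmrs:
        iv = hmr.interval
        if any(iv.contains_position(bp) for bp in rearrangement_map.breakpoints):
            continue
        if any(iv.overlaps(d) for d in rearrangement_map.deleted):
            continue
        copy_number = None
        for dup, cn in rearrangement_map.duplicated:
            if iv.overlaps(dup):
                copy_number = cn
                break
        if copy_number is not None:
            hmr = Hmr(
                interval=hmr.interval,
                summit=hmr.summit,
                p_value=hmr.p_value,
                reads_by_sample={
                    k: v / copy_number for k, v in hmr.reads_by_sample.items()
                },
                label=hmr.label,
                fold=hmr.fold,
            )
        out.append(hmr)
    return out
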