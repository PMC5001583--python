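"""Sequence features and repeat ages of HMR classes.

CpG density is reported as CpGs per 100 bp of interval (a per-length rate,
not an observed/expected ratio); GC content as a fraction of unambiguous
bases.  The background control shifts each HMR to a uniformly random,
non-excluded position of the same contig, preserving the interval-length
multiset exactly.  Repeat age follows the molecular-clock estimate
``(milliDiv / 1000) / mutation_rate`` with a default mammalian neutral rate
of 2.2e-9 substitutions per site per year; HMRs are assigned a repeat age
when their summit base falls inside an annotated repeat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomicInterval, RepeatElement
from .hmr_detection import Hmr

__all__ = [
    "RepeatAgeParams",
    "cpg_density",
    "gc_content",
    "shifted_background",
    "repeat_age",
    "summit_repeat_ages",
    "compare_age_groups",
]


@dataclass
class RepeatAgeParams:
    #: substitutions per site per year (mammalian neutral rate)
    mutation_rate: float = 2.2e-9

    def __post_init__(self):
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be positive")


def cpg_density(seq: str) -> float:
    """CpGs per 100 bp; dinucleotides containing non-ACGT letters skipped."""
    if len(seq) < 2:
        raise ValueError("sequence must be at least 2 bp")
    s = seq.upper()
    count = sum(1 for i in range(len(s) - 1) if s[i] == "C" and s[i + 1] == "G")
    return 100.0 * count / len(s)


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); ambiguous letters excluded entirely."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def shifted_background(
    intervals: Sequence[GenomicInterval],
    contig_length: int,
    excluded: Sequence[GenomicInterval] = (),
    seed: int = 0,
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    """Length-matched random control intervals avoiding the excluded set.

    Each source interval is re-placed at a uniformly random start on the
    same contig (rejection sampling against ``excluded``); output lengths
    equal input lengths exactly, and the result is seed-deterministic.
    """
    rng = np.random.default_rng(seed)
    exc_starts = np.array(sorted(e.start for e in excluded), dtype=np.int64)
    exc_sorted = sorted(excluded, key=lambda e: e.start)
    exc_ends = np.array([e.end for e in exc_sorted], dtype=np.int64)

    def _clashes(start: int, end: int) -> bool:
        if exc_starts.size == 0:
            return False
        i = np.searchsorted(exc_starts, end)
        return bool(np.any(exc_ends[:i] > start))

    out: list[GenomicInterval] = []
    for iv in intervals:
        if iv.length >= contig_length:
            raise ValueError(f"interval {iv} is not shorter than the contig")
        for _ in range(max_tries):
            start = int(rng.integers(0, contig_length - iv.length + 1))
            if not _clashes(start, start + iv.length):
                out.append(GenomicInterval(iv.contig, start, start + iv.length))
                break
        else:
            raise RuntimeError(
                f"could not place shifted control for {iv.contig}:"
                f"{iv.start}-{iv.end} after {max_tries} tries"
            )
    return out


def repeat_age(milli_div: int, params: RepeatAgeParams | None = None) -> float:
    """Age in years: per-site divergence divided by the mutation rate."""
    params = params or RepeatAgeParams()
    if milli_div < 0:
        raise ValueError("milliDiv must be >= 0")
    return (milli_div / 1000.0) / params.mutation_rate


def summit_repeat_ages(
    hmrs: Sequence[Hmr],
    repeats: Sequence[RepeatElement],
    params: RepeatAgeParams | None = None,
) -> dict[str, np.ndarray]:
    """Repeat ages of HMRs whose summit base lies inside a repeat, by label.

    The summit is a point query: an HMR contributes one age sample when a
    repeat on the same contig contains its summit position.
    """
    params = params or RepeatAgeParams()
    samples: dict[str, list[float]] = {}
    by_contig: dict[str, list[RepeatElement]] = {}
    for rep in repeats:
        by_contig.setdefault(rep.interval.contig, []).append(rep)
    for hmr in hmrs:
        for rep in by_contig.get(hmr.interval.contig, ()):
            if rep.interval.contains_position(hmr.summit):
                samples.setdefault(hmr.label, []).append(
                    repeat_age(rep.milli_div, params)
                )
                break
    return {label: np.array(ages) for label, ages in samples.items()}


def compare_age_groups(
    ages_by_label: dict[str, np.ndarray], label1: str, label2: str
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two label groups.

    Exact null distribution for small groups (both sizes <= 20), normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(ages_by_label.get(label1, ()), dtype=float)
    y = np.asarray(ages_by_label.get(label2, ()), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(x.size, y.size) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
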