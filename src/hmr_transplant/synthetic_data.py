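"""Synthetic composite genome and methylome generator.

Emulates a transplanted-chromosome experiment: one donor contig carried in
two different host nuclear environments ("A" and "B") that share identical
DNA sequence but may differ in methylation state.  The generator plants three
mechanistic classes of hypomethylated element on the donor contig:

* **shared CGIs** — CpG- and GC-rich 1–2 kb islands, unmethylated in both
  hosts (the classical promoter-associated class; most carry a TSS and are
  covered by an old, diverged repeat so that repeat-age contrasts have
  recoverable ground truth);
* **young CpG-rich repeats** — elements whose high CpG density protects them
  from methylation only in the host that lacks co-evolved repeat-defense
  machinery; they are hypomethylated in exactly one context and carry a low
  milliDiv (little divergence from consensus = young);
* **TF-protected elements** — intermediate-CpG distal elements protected by
  a transcription-factor binding event present in only one context; they are
  hypomethylated exactly where the factor is bound.

Everything else is methylated at a high background level.  BioCAP capture is
modeled at the fragment level: a fragment's sampling weight is the expected
number of unmethylated CpGs it contains, Sigma(1 - m_i), plus a small uniform
background rate.  Bisulfite counts are binomial draws with incomplete
conversion, plus fully-unmethylated and fully-methylated spike-in controls.

Identical config (including seed) gives byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import (
    CoverageTrack,
    GenomicInterval,
    MethCall,
    RepeatElement,
    cpg_positions,
)
from .hmr_detection import RearrangementMap
from .overlap_annotation import TfPeak

__all__ = [
    "SimConfig",
    "Methylome",
    "PlantedElement",
    "GenomeBundle",
    "SimulationSizeError",
    "simulate_composite_genome",
    "simulate_biocap_coverage",
    "simulate_input_control",
    "simulate_bisulfite_counts",
]

_TF_FACTORS = ("CEBPA", "HNF4A", "CTCF")
MIN_FRAGMENT_LEN = 50


class SimulationSizeError(ValueError):
    """Planted element footprints do not fit on the transplanted contig."""


@dataclass
class SimConfig:
    """Study conditions for one simulated transplantation experiment.

    Defaults describe a 2 Mb donor contig carrying 60 shared CGIs and 20
    context-specific elements per host, sequenced at 30x mean BioCAP
    fragment coverage — a desk-scale stand-in for a ~42 Mb transplanted
    chromosome.
    """

    seed: int = 0
    transplant_length: int = 2_000_000
    host_length: int = 200_000
    n_shared_cgis: int = 60
    n_a_specific: int = 20
    n_b_specific: int = 20
    #: total young CpG-rich repeat elements, split evenly between the two
    #: context-specific sets; the remaining specific elements are TF-protected
    n_young_repeats: int = 20
    n_tf_sites_per_context: int = 30
    cgi_length_range: tuple[int, int] = (1000, 2000)
    background_cpg_rate: float = 0.008
    cgi_cpg_rate: float = 0.08
    young_repeat_cpg_rate: float = 0.12
    tf_element_cpg_rate: float = 0.03
    background_gc: float = 0.40
    island_gc: float = 0.60
    #: Beta(alpha, beta) for methylated background CpGs (mean ~= 0.85)
    background_meth: tuple[float, float] = (8.5, 1.5)
    #: Beta(alpha, beta) for hypomethylated-element CpGs (mean ~= 0.05)
    hmr_meth: tuple[float, float] = (0.5, 9.5)
    biocap_depth: float = 30.0
    biocap_background_rate: float = 0.001
    fragment_len_mean: float = 200.0
    fragment_len_sd: float = 40.0
    bisulfite_depth: int = 50
    conversion_rate: float = 0.99
    tss_fraction: float = 0.7
    n_breakpoints: int = 0
    n_deleted: int = 0
    n_duplicated: int = 0
    contexts: tuple[str, str] = ("A", "B")
    transplant_contig: str = "chrT"
    host_contig: str = "chrHost"

    def validate(self) -> None:
        counts = {
            "n_shared_cgis": self.n_shared_cgis,
            "n_a_specific": self.n_a_specific,
            "n_b_specific": self.n_b_specific,
            "n_young_repeats": self.n_young_repeats,
            "n_tf_sites_per_context": self.n_tf_sites_per_context,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        for name in (
            "background_cpg_rate",
            "cgi_cpg_rate",
            "young_repeat_cpg_rate",
            "tf_element_cpg_rate",
            "background_gc",
            "island_gc",
            "tss_fraction",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not (0.0 < self.conversion_rate <= 1.0):
            raise ValueError("conversion_rate must lie in (0, 1]")
        lo, hi = self.cgi_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad cgi_length_range {self.cgi_length_range}")


@dataclass
class Methylome:
    """Ground-truth per-CpG methylation probability for one host context.

    ``levels[contig]`` is a pair of parallel arrays: the CpG positions of
    the contig (C of the forward-strand dyad) and their probabilities.
    """

    levels: dict[str, tuple[np.ndarray, np.ndarray]]

    def positions(self, contig: str) -> np.ndarray:
        return self.levels[contig][0]

    def values(self, contig: str) -> np.ndarray:
        return self.levels[contig][1]

    def mean_level(self, contig: str, start: int, end: int) -> float:
        pos, m = self.levels[contig]
        lo, hi = np.searchsorted(pos, (start, end))
        if hi == lo:
            return float("nan")
        return float(m[lo:hi].mean())


@dataclass(frozen=True)
class PlantedElement:
    """Truth record for one planted element on the donor contig."""

    interval: GenomicInterval
    #: "shared", "A", or "B" — contexts in which the element is hypomethylated
    hypomethylated_in: str
    #: "cgi", "young_repeat", or "tf_protected"
    mechanism: str


@dataclass
class GenomeBundle:
    """Everything one simulated experiment knows to be true."""

    sequences: dict[str, str]
    cgi_truth: list[GenomicInterval]
    repeat_truth: list[RepeatElement]
    tss_truth: list[GenomicInterval]
    tf_truth_by_context: dict[str, list[TfPeak]]
    methylome_by_context: dict[str, Methylome]
    rearrangement_map: RearrangementMap
    planted_elements: list[PlantedElement]
    config: SimConfig

    def hypomethylated_elements(self, context: str) -> list[PlantedElement]:
        """Planted elements that are unmethylated in the given context."""
        return [
            el
            for el in self.planted_elements
            if el.hypomethylated_in in ("shared", context)
        ]


# ---------------------------------------------------------------------------
# Sequence construction

_A, _C, _G, _T = ord("A"), ord("C"), ord("G"), ord("T")
_BASES = np.array([_A, _C, _G, _T], dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float, cpg_rate: float) -> np.ndarray:
    """i.i.d. bases at the requested GC, then thinned/enriched to a target
    forward-strand CpG rate (CpGs per bp)."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = _BASES[rng.choice(4, size=length, p=probs)]
    if length < 2:
        return arr
    cg = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
    natural = cg.size / length
    if natural > cpg_rate and cg.size:
        keep = rng.random(cg.size) < cpg_rate / natural
        kill = cg[~keep]
        # mutate the G away; replacement drawn from A/T to deepen depletion
        arr[kill + 1] = np.where(rng.random(kill.size) < 0.5, _A, _T).astype(np.uint8)
    elif natural < cpg_rate:
        n_add = int(round((cpg_rate - natural) * length))
        if n_add > 0:
            pos = rng.choice(length - 1, size=min(n_add, length - 1), replace=False)
            arr[pos] = _C
            arr[pos + 1] = _G
    return arr


def _seq_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Genome assembly


def simulate_composite_genome(config: SimConfig) -> GenomeBundle:
    """Build the composite genome, truth annotations and both methylomes.

    Raises :class:`SimulationSizeError` when the requested element counts do
    not fit on the transplanted contig at the configured lengths.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.transplant_length
    lo_len, hi_len = config.cgi_length_range

    n_young_a = min(config.n_young_repeats // 2, config.n_a_specific)
    n_young_b = min(config.n_young_repeats - config.n_young_repeats // 2, config.n_b_specific)
    n_tf_a = config.n_a_specific - n_young_a
    n_tf_b = config.n_b_specific - n_young_b
    n_elements = config.n_shared_cgis + config.n_a_specific + config.n_b_specific
    n_extra_tf = 2 * max(0, config.n_tf_sites_per_context - max(n_tf_a, n_tf_b))
    n_rearr = config.n_breakpoints + config.n_deleted + config.n_duplicated
    n_slots_needed = n_elements + n_extra_tf + n_rearr

    margin = 3000
    slot_pitch = hi_len + margin
    n_slots = max(0, (L - 2 * margin) // slot_pitch)
    if n_slots < n_slots_needed:
        raise SimulationSizeError(
            f"transplant_length={L} fits {n_slots} element slots but "
            f"{n_slots_needed} are required (n_shared_cgis={config.n_shared_cgis}, "
            f"n_a_specific={config.n_a_specific}, n_b_specific={config.n_b_specific}, "
            f"extra TF sites={n_extra_tf}, rearrangements={n_rearr})"
        )
    slot_starts = margin + slot_pitch * rng.permutation(n_slots)[:n_slots_needed]

    transplant = _random_seq(rng, L, config.background_gc, config.background_cpg_rate)
    host = _random_seq(rng, config.host_length, config.background_gc, config.background_cpg_rate)

    planted: list[PlantedElement] = []
    cgi_truth: list[GenomicInterval] = []
    repeat_truth: list[RepeatElement] = []
    tss_truth: list[GenomicInterval] = []
    tf_by_context: dict[str, list[TfPeak]] = {c: [] for c in config.contexts}
    ctg = config.transplant_contig
    ctx_a, ctx_b = config.contexts

    slot_iter = iter(slot_starts)

    def _place(length: int) -> GenomicInterval:
        start = int(next(slot_iter)) + int(rng.integers(0, margin // 2))
        return GenomicInterval(ctg, start, start + length)

    def _plant_sequence(iv: GenomicInterval, cpg_rate: float, gc: float) -> None:
        transplant[iv.start : iv.end] = _random_seq(rng, iv.length, gc, cpg_rate)

    # shared CGIs: CpG-rich, most with a TSS, each covered by an old repeat
    for i in range(config.n_shared_cgis):
        iv = _place(int(rng.integers(lo_len, hi_len + 1)))
        iv = GenomicInterval(ctg, iv.start, iv.end, name=f"shared_cgi_{i}")
        _plant_sequence(iv, config.cgi_cpg_rate, config.island_gc)
        cgi_truth.append(iv)
        planted.append(PlantedElement(iv, "shared", "cgi"))
        repeat_truth.append(
            RepeatElement(
                GenomicInterval(ctg, iv.start, iv.end, name=f"L2sim_{i}"),
                family="L2sim",
                milli_div=int(rng.integers(150, 301)),
            )
        )
        if rng.random() < config.tss_fraction:
            mid = (iv.start + iv.end) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            tss_truth.append(
                GenomicInterval(ctg, mid, mid + 1, name=f"tss_{i}", strand=strand)
            )

    def _plant_specific(context: str, n_young: int, n_tf: int) -> None:
        for j in range(n_young):
            iv = _place(int(rng.integers(lo_len, hi_len + 1)))
            iv = GenomicInterval(ctg, iv.start, iv.end, name=f"{context}_repeat_{j}")
            _plant_sequence(iv, config.young_repeat_cpg_rate, config.island_gc)
            planted.append(PlantedElement(iv, context, "young_repeat"))
            repeat_truth.append(
                RepeatElement(
                    GenomicInterval(ctg, iv.start, iv.end, name=f"AluYsim_{context}{j}"),
                    family="AluYsim",
                    milli_div=int(rng.integers(0, 51)),
                )
            )
        for j in range(n_tf):
            iv = _place(int(rng.integers(lo_len, hi_len + 1)))
            iv = GenomicInterval(ctg, iv.start, iv.end, name=f"{context}_tf_{j}")
            _plant_sequence(iv, config.tf_element_cpg_rate, config.background_gc)
            planted.append(PlantedElement(iv, context, "tf_protected"))
            mid = (iv.start + iv.end) // 2
            factor = _TF_FACTORS[j % len(_TF_FACTORS)]
            tf_by_context[context].append(
                TfPeak(GenomicInterval(ctg, mid - 100, mid + 100), factor, context)
            )

    _plant_specific(ctx_a, n_young_a, n_tf_a)
    _plant_specific(ctx_b, n_young_b, n_tf_b)

    # extra background TF sites so each context reaches its configured count
    for context in config.contexts:
        while len(tf_by_context[context]) < config.n_tf_sites_per_context:
            start = int(next(slot_iter)) + int(rng.integers(0, margin // 2))
            factor = _TF_FACTORS[int(rng.integers(len(_TF_FACTORS)))]
            tf_by_context[context].append(
                TfPeak(GenomicInterval(ctg, start, start + 200), factor, context)
            )

    # optional rearrangements in free background slots
    breakpoints: list[int] = []
    deleted: list[GenomicInterval] = []
    duplicated: list[tuple[GenomicInterval, int]] = []
    for _ in range(config.n_breakpoints):
        breakpoints.append(int(next(slot_iter)))
    for _ in range(config.n_deleted):
        start = int(next(slot_iter))
        deleted.append(GenomicInterval(ctg, start, start + 1000))
    for _ in range(config.n_duplicated):
        start = int(next(slot_iter))
        duplicated.append((GenomicInterval(ctg, start, start + 1000), 2))
    rearrangement_map = RearrangementMap(
        breakpoints=breakpoints, deleted=deleted, duplicated=duplicated
    )

    sequences = {ctg: _seq_to_str(transplant), config.host_contig: _seq_to_str(host)}

    # methylomes: background Beta everywhere, overridden inside elements
    methylomes: dict[str, Methylome] = {}
    for context in config.contexts:
        levels: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, seq in sequences.items():
            pos = cpg_positions(seq)
            m = rng.beta(*config.background_meth, size=pos.size)
            if contig == ctg:
                for el in planted:
                    if el.hypomethylated_in in ("shared", context):
                        lo, hi = np.searchsorted(pos, (el.interval.start, el.interval.end))
                        m[lo:hi] = rng.beta(*config.hmr_meth, size=hi - lo)
            levels[contig] = (pos, np.clip(m, 0.0, 1.0))
        methylomes[context] = Methylome(levels)

    return GenomeBundle(
        sequences=sequences,
        cgi_truth=cgi_truth,
        repeat_truth=repeat_truth,
        tss_truth=tss_truth,
        tf_truth_by_context=tf_by_context,
        methylome_by_context=methylomes,
        rearrangement_map=rearrangement_map,
        planted_elements=planted,
        config=config,
    )


# ---------------------------------------------------------------------------
# Coverage simulation


def _sample_fragments(
    rng: np.random.Generator,
    weight_density: np.ndarray,
    n_fragments: int,
    frag_mean: float,
    frag_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw fragment (start, end) pairs with start probability proportional
    to the density summed over a nominal fragment window."""
    L = weight_density.size
    fl = int(round(frag_mean))
    if L <= fl:
        raise ValueError("contig shorter than one fragment")
    cs = np.concatenate(([0.0], np.cumsum(weight_density)))
    window_weight = cs[fl:] - cs[:-fl]  # weight of [s, s+fl) for each start s
    total = window_weight.sum()
    if total <= 0:
        raise ValueError("no capture weight anywhere on the contig")
    starts = rng.choice(window_weight.size, size=n_fragments, p=window_weight / total)
    lengths = np.maximum(
        MIN_FRAGMENT_LEN, np.rint(rng.normal(frag_mean, frag_sd, size=n_fragments))
    ).astype(np.int64)
    ends = np.minimum(starts + lengths, L)
    return starts.astype(np.int64), ends


def _coverage_from_fragments(L: int, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    diff = np.zeros(L + 1, dtype=np.float64)
    np.add.at(diff, starts, 1.0)
    np.add.at(diff, ends, -1.0)
    return np.cumsum(diff[:-1])


def simulate_biocap_coverage(
    bundle: GenomeBundle,
    context: str,
    replicate_seed: int,
    depth: float | None = None,
    contig: str | None = None,
) -> CoverageTrack:
    """Simulate one BioCAP replicate for one contig of one host context.

    Capture chemistry is abstracted to a linear weight: a fragment is
    sampled with probability proportional to its expected unmethylated-CpG
    content Sigma(1 - m_i) plus ``biocap_background_rate`` per base.
    Distinct ``replicate_seed`` values give independent noise around the
    same expectation.
    """
    if context not in bundle.methylome_by_context:
        raise KeyError(f"unknown context {context!r}")
    config = bundle.config
    if depth is None:
        depth = config.biocap_depth
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    contig = contig or config.transplant_contig
    L = len(bundle.sequences[contig])
    methylome = bundle.methylome_by_context[context]
    pos, m = methylome.levels[contig]

    density = np.full(L, config.biocap_background_rate, dtype=np.float64)
    density[pos] += 1.0 - m

    rng = np.random.default_rng(replicate_seed)
    n_fragments = int(round(depth * L / config.fragment_len_mean))
    starts, ends = _sample_fragments(
        rng, density, n_fragments, config.fragment_len_mean, config.fragment_len_sd
    )
    values = _coverage_from_fragments(L, starts, ends)
    return CoverageTrack(contig=contig, values=values, total_reads=float(n_fragments))


def simulate_input_control(
    bundle: GenomeBundle,
    seed: int,
    depth: float | None = None,
    contig: str | None = None,
) -> CoverageTrack:
    """Uniform fragment sampling with no methylation weighting."""
    config = bundle.config
    if depth is None:
        depth = config.biocap_depth
    if depth < 0:
        raise ValueError(f"depth must be non-negative, got {depth}")
    contig = contig or config.transplant_contig
    L = len(bundle.sequences[contig])
    n_fragments = int(round(depth * L / config.fragment_len_mean))
    if n_fragments == 0:
        return CoverageTrack(contig=contig, values=np.zeros(L), total_reads=0.0)
    rng = np.random.default_rng(seed)
    starts, ends = _sample_fragments(
        rng,
        np.ones(L, dtype=np.float64),
        n_fragments,
        config.fragment_len_mean,
        config.fragment_len_sd,
    )
    values = _coverage_from_fragments(L, starts, ends)
    return CoverageTrack(contig=contig, values=values, total_reads=float(n_fragments))


# ---------------------------------------------------------------------------
# Bisulfite simulation

_SPIKE_LENGTH = 10_000


def simulate_bisulfite_counts(
    bundle: GenomeBundle,
    context: str,
    amplicons: Sequence[GenomicInterval],
    depth: int | None = None,
    conversion_rate: float | None = None,
    seed: int = 0,
) -> tuple[list[MethCall], list[MethCall], list[MethCall]]:
    """Binomial bisulfite counts for each CpG in each amplicon, plus two
    spike-in control sets.

    The observed methylated-read probability at a CpG with true level ``m``
    is ``m + (1 - m) * (1 - conversion_rate)``: a truly methylated cytosine
    always survives conversion, an unmethylated one fails to convert with
    probability ``1 - conversion_rate``.  The spike-ins are synthetic 10 kb
    CpG-bearing contigs, one fully unmethylated (m = 0) and one fully
    methylated (m = 1), emulating conversion-control DNA added to the same
    reaction.

    Returns ``(amplicon_calls, unmethylated_spikein, methylated_spikein)``.
    """
    config = bundle.config
    if depth is None:
        depth = config.bisulfite_depth
    if conversion_rate is None:
        conversion_rate = config.conversion_rate
    if not (0.0 < conversion_rate <= 1.0):
        raise ValueError("conversion_rate must lie in (0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if context not in bundle.methylome_by_context:
        raise KeyError(f"unknown context {context!r}")
    methylome = bundle.methylome_by_context[context]
    rng = np.random.default_rng(seed)

    def _draw(contig: str, positions: np.ndarray, m: np.ndarray) -> list[MethCall]:
        p_obs = m + (1.0 - m) * (1.0 - conversion_rate)
        meth = rng.binomial(depth, p_obs)
        return [
            MethCall(contig, int(p), int(k), int(depth - k))
            for p, k in zip(positions, meth)
        ]

    calls: list[MethCall] = []
    for amp in amplicons:
        if amp.contig not in bundle.sequences:
            raise KeyError(f"amplicon on unknown contig {amp.contig!r}")
        if amp.end > len(bundle.sequences[amp.contig]):
            raise ValueError(f"amplicon {amp} beyond contig end")
        pos, m = methylome.levels[amp.contig]
        lo, hi = np.searchsorted(pos, (amp.start, amp.end))
        if hi == lo:
            warnings.warn(
                f"amplicon {amp.contig}:{amp.start}-{amp.end} contains no CpG",
                stacklevel=2,
            )
            continue
        calls.extend(_draw(amp.contig, pos[lo:hi], m[lo:hi]))

    # conversion-control spike-ins: deterministic sequence from this seed
    spike_rng = np.random.default_rng(seed + 1)
    spike_seq = _seq_to_str(_random_seq(spike_rng, _SPIKE_LENGTH, 0.5, 0.05))
    spike_pos = cpg_positions(spike_seq)
    spike_unmeth = _draw("spikein_unmeth", spike_pos, np.zeros(spike_pos.size))
    spike_meth = _draw("spikein_meth", spike_pos, np.ones(spike_pos.size))
    return calls, spike_unmeth, spike_meth
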