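# Methods

## The measurement being emulated

CxxC-affinity capture (BioCAP) enriches DNA fragments containing
non-methylated CpG dinucleotides: a ZF-CxxC protein domain binds unmethylated
CpGs, so sequencing the captured material maps hypomethylated regions (HMRs)
genome-wide. In a transplanted-chromosome design the same donor sequence is
profiled in two host nuclear environments, and the comparison separates
DNA-encoded methylation logic (shared HMRs) from host-dependent mechanisms
(species-specific HMRs).

## Simulator

`synthetic_data.simulate_composite_genome` builds a donor contig (default
2 Mb) plus a small host contig. Sequence is drawn i.i.d. at a target GC
content, then CpG dinucleotides are thinned or enriched to a target
forward-strand CpG rate; the defaults (background 0.8 CpG/100 bp at 40% GC,
islands ≈ 8/100 bp at 60% GC) reproduce the strong CpG depletion of
vertebrate bulk sequence against CpG-island-like elements. Planted elements
are 1–2 kb, placed on a randomized non-overlapping grid with 3 kb margins:

- **shared CGIs** (default 60): unmethylated in both hosts; ~70% carry a TSS
  at their midpoint; each is covered by an old repeat annotation
  (milliDiv ~ U(150, 300)) so repeat-age contrasts have ground truth;
- **young CpG-rich repeats** (default 10 per host): CpG rate ≈ 12/100 bp —
  deliberately above the shared-CGI rate, since recently expanded repeats
  have not yet lost their CpGs — hypomethylated only in the host lacking
  repeat-defense, milliDiv ~ U(0, 50);
- **TF-protected elements** (default 10 per host): intermediate CpG rate
  (≈ 3/100 bp), hypomethylated only in the host where a TF site (CEBPA /
  HNF4A / CTCF, 200 bp) is planted inside the element.

Methylation truth is per-CpG: background Beta(8.5, 1.5) (mean 0.85),
hypomethylated elements Beta(0.5, 9.5) (mean 0.05). The species-specific
state is planted *mechanistically* (repeat-defense present/absent, TF
bound/unbound) so the downstream explanatory analyses have recoverable
truth, not just labels.

**Capture model.** A fragment starting at `s` with nominal length `f` is
sampled with probability proportional to
`Σ_{CpG i in [s, s+f)} (1 − m_i) + r·f`, where `r` (default 0.001/bp) is a
uniform background-capture rate. Fragment lengths are Normal(200, 40)
truncated at 50 bp. This linear weight is a modelling choice — capture
efficiency is not characterized quantitatively by the assay — but it yields
the two properties that matter: expected coverage increases with
unmethylated-CpG content, and a fully methylated genome gives flat
background. The input control uses uniform weight. One consequence worth
knowing: a *background* methylome at mean 0.85 still leaves ~15% weight per
CpG, so random CpG clusters in background sequence form weak but genuine
enrichment islands; a run with nothing planted therefore reports a handful
of background HMRs unless the background is fully methylated. This mirrors
the weak background islands seen in real capture data.

**Bisulfite model.** Observed methylated-read probability at a CpG with true
level `m` is `m + (1−m)(1−c)` for conversion rate `c` (default 0.99);
counts are Binomial(depth). Spike-in controls are synthetic 10 kb contigs at
`m = 0` and `m = 1` passed through the same conversion arithmetic — only the
conversion accounting, not the biological source, matters. Per-CpG accuracy
is depth-limited: at 50× the binomial sd at an intermediate level (m = 0.2)
is 5.7 percentage points, so ±5-point per-CpG recovery for ≥95% of CpGs
requires ≥ ~100×; the test suite checks the property at 100× and the
simulated 0.99 conversion is recovered within ±0.002 from spike-ins pooled
over ~500 CpGs at 1000×.

## Peak caller

Every sliding window of width `bandwidth` (default 300 bp) is scored. The
window's fragment count is estimated as coverage-sum divided by the track's
mean fragment length (`values.sum()/total_reads`) and rounded half-up to an
integer. The null rate is
`λ_local = max(λ_BG, λ_1k, λ_5k, λ_10k)` with `λ_BG = N·(bw+f)/G`
(`G` = effective genome size, default 4.8e8 as is conventional for this
assay) and the local terms estimated from the input control over windows
centered on the same point, rescaled to the window footprint and to the
treatment depth (`× N_t/N_c`). Windows with Poisson upper-tail
`P(X ≥ obs) ≤ 1e-5` are merged, bridging gaps ≤ 100 bp; each peak carries
the leftmost-maximum summit and its best window p-value. The mfold filter
(enrichment ≥ 10 over `λ_BG`) prunes candidates before scoring; at the
default `G` it is inert, which is exactly what makes the vectorized caller
provably identical to an exhaustive per-window scorer (a property the test
suite checks on constructed tracks). There is no tag-shift model: capture
yields fragments directly, so ChIP-style shift estimation does not apply.
No multiple-testing correction is applied — the fixed p-value cutoff is the
standard operating point for this caller family. Peaks must be reproduced
(≥ 1 bp overlap) in both biological replicates; HMRs overlapping assembly
breakpoints or deleted regions are removed, and read counts inside
duplicated regions are divided by copy number.

## Differential classification

Classification operates on the union of the two hosts' HMR sets (maximal
merged intervals) so partially-overlapping peaks are counted once. Fragment
counts over each union interval are estimated from pooled replicate
coverage, context B is rescaled to context A's depth, and
`fold = (n_A + 1)/(n_B' + 1)` with a pseudocount of 1 — the generator's
counts are in the hundreds-to-thousands, so the pseudocount only guards
zero-count intervals. Raw overlapping-fragment counts (not length-normalized)
are used, matching read-count semantics. The summit of a classified interval
is the leftmost maximum of the summed coverage.

## Feature analyses

CpG density is reported as CpGs per 100 bp (the plotted quantity is a
per-length rate, not an observed/expected ratio — a deliberate, documented
choice). Background controls shift each HMR to a uniformly random
non-excluded position of the same contig, preserving lengths exactly
(rejection sampling, 10⁴ tries, seed-deterministic). Repeat age is
`(milliDiv/1000)/μ` with `μ = 2.2e-9` substitutions/site/year; an HMR
contributes an age sample when its summit base (point query) falls inside an
annotated repeat, with Mann–Whitney U between label groups (exact null for
group sizes ≤ 20, normal approximation above). TSS association is any
overlap with the 1001-position footprint `[tss−500, tss+500]`; TF-peak
specificity is factor-stratified any-overlap intersection across hosts;
Venn percentages are rounded half-up to integers as is conventional when
reporting such overlaps.

## Determinism and problem sizes

Every stochastic function takes an explicit seed; the pipeline derives all
stage seeds from one run seed by fixed offsets, so reruns are byte-identical
(JSON reports are written with sorted keys). The packaged defaults — 2 Mb
donor contig, 100 planted elements, 30× coverage — are a desk-scale design:
large enough that per-element counts are in the hundreds (binomial/Poisson
noise a few percent) and all class contrasts are resolvable, small enough
that a full two-host, two-replicate analysis runs in seconds. The pipeline
test configuration scales down further (250 kb, 16 elements).

## Known limitations

- Capture efficiency is linear in unmethylated-CpG count with no saturation,
  no fragment-GC bias, and no mappability structure.
- Read-level artifacts (sequencing error, PCR duplicates, alignment) are out
  of scope; the simulator emits coverage and counts directly.
- The two hosts differ only in methylome; sequence is identical by
  construction, so host-genome alignment issues do not arise.
- Counts over union intervals are estimated from coverage mass divided by
  mean fragment length, a slight underestimate of true overlapping-fragment
  counts near interval edges; it cancels in fold ratios.
- Passing recovery tests on this generator demonstrates the pipeline's
  arithmetic and decision rules, not robustness to the full noise structure
  of real capture libraries.
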