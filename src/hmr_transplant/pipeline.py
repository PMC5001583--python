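"""End-to-end orchestration: simulate -> call -> classify -> profile ->
annotate -> validate, with every intermediate written to disk and a
machine-readable JSON report.

All stochastic stages derive their seeds from ``RunConfig.seed`` by fixed
small offsets, so a rerun with the same config is byte-identical.  Each stage
reads only what the previous stage wrote (or returned), so stages can be
rerun individually from their on-disk inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import bisulfite as bs
from . import differential as diff
from . import feature_profiles as fp
from . import hmr_detection as hd
from . import io_formats as iof
from . import overlap_annotation as oa
from . import synthetic_data as sd

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("hmr_transplant")

# fixed seed offsets for the stochastic stages (replicates, controls, ...)
_SEED_REP = {("A", 1): 11, ("A", 2): 12, ("B", 1): 21, ("B", 2): 22}
_SEED_INPUT = {"A": 31, "B": 32}
_SEED_BISULFITE = {"A": 41, "B": 42}
_SEED_SHIFT = 51


@dataclass
class RunConfig:
    sim: sd.SimConfig = field(default_factory=sd.SimConfig)
    peaks: hd.PeakCallParams = field(default_factory=hd.PeakCallParams)
    differential: diff.DifferentialParams = field(default_factory=diff.DifferentialParams)
    annotation: oa.AnnotationParams = field(default_factory=oa.AnnotationParams)
    repeat_age: fp.RepeatAgeParams = field(default_factory=fp.RepeatAgeParams)
    outdir: str = "hmr_transplant_run"
    seed: int = 0

    def __post_init__(self):
        # one seed drives everything; the sim config inherits it
        self.sim.seed = self.seed


def _hmrs_to_bed(hmrs, path):
    rows = []
    for h in hmrs:
        iv = h.interval
        score = 0.0 if not np.isfinite(h.p_value) else -np.log10(max(h.p_value, 1e-300))
        reads = ";".join(f"{k}={v:.3f}" for k, v in sorted(h.reads_by_sample.items()))
        rows.append(
            f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score:.4g}\t.\t"
            f"{h.summit - iv.start}\t{h.label}\t{reads}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(rows)


def _fraction_recapitulated(hmrs_from, hmrs_in) -> float | None:
    """Fraction of one context's HMRs overlapped by an HMR of the other."""
    if not hmrs_from:
        return None
    hits = hd.intersect_replicates(list(hmrs_from), list(hmrs_in))
    return len(hits) / len(hmrs_from)


def _pool_replicates(tracks):
    values = sum(t.values for t in tracks)
    total = sum(t.total_reads for t in tracks)
    return iof.CoverageTrack(contig=tracks[0].contig, values=values, total_reads=total)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}
    ctx_a, ctx_b = config.sim.contexts

    def _stage(name):
        log.info("stage %s", name)

    # ---- simulate -------------------------------------------------------
    try:
        _stage("simulate")
        bundle = sd.simulate_composite_genome(config.sim)
        iof.save_fasta(bundle.sequences, outdir / "genome.fa")
        iof.save_intervals(bundle.cgi_truth, outdir / "cgi_truth.bed")
        iof.save_repeats(bundle.repeat_truth, outdir / "repeats.bed")
        iof.save_intervals(bundle.tss_truth, outdir / "tss.bed")
        for ctx, peaks in bundle.tf_truth_by_context.items():
            iof.save_intervals(
                [
                    iof.GenomicInterval(
                        p.interval.contig, p.interval.start, p.interval.end, p.factor
                    )
                    for p in peaks
                ],
                outdir / f"tf_{ctx}.bed",
            )
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", exc) from exc

    # ---- coverage + peak calling ---------------------------------------
    try:
        _stage("callhmr")
        cov: dict = {}
        hmrs_by_context: dict = {}
        for ctx in (ctx_a, ctx_b):
            reps = []
            for rep in (1, 2):
                track = sd.simulate_biocap_coverage(
                    bundle, ctx, replicate_seed=config.seed + _SEED_REP[(ctx, rep)]
                )
                iof.save_coverage(track, outdir / f"biocap_{ctx}_rep{rep}.bedGraph")
                reps.append(track)
            control = sd.simulate_input_control(
                bundle, seed=config.seed + _SEED_INPUT[ctx]
            )
            iof.save_coverage(control, outdir / f"input_{ctx}.bedGraph")
            peaks = [
                hd.call_peaks(t, control, config.peaks, sample_id=f"{ctx}_rep{i+1}")
                for i, t in enumerate(reps)
            ]
            reproducible = hd.intersect_replicates(peaks[0], peaks[1])
            reproducible = hd.apply_rearrangement_map(
                reproducible, bundle.rearrangement_map
            )
            hmrs_by_context[ctx] = reproducible
            cov[ctx] = _pool_replicates(reps)
            _hmrs_to_bed(reproducible, outdir / f"hmrs_{ctx}.bed")
        report["n_hmrs_by_context"] = {
            ctx: len(h) for ctx, h in hmrs_by_context.items()
        }
    except Exception as exc:
        raise StageError("callhmr", exc) from exc

    # ---- differential classification -----------------------------------
    try:
        _stage("classify")
        union = diff.merge_union(hmrs_by_context[ctx_a], hmrs_by_context[ctx_b])
        if union:
            classified = diff.classify_hmrs(
                union, cov[ctx_a], cov[ctx_b], config.differential
            )
        else:
            classified = []
        _hmrs_to_bed(classified, outdir / "hmrs_classified.bed")
        label_counts = {"shared": 0, "A_specific": 0, "B_specific": 0}
        for h in classified:
            label_counts[h.label] += 1
        report["n_union_hmrs"] = len(classified)
        report["label_counts"] = label_counts
        # headline recapitulation statistic: context-A HMRs re-formed in B
        report["fraction_shared"] = _fraction_recapitulated(
            hmrs_by_context[ctx_a], hmrs_by_context[ctx_b]
        )
        report["fraction_recapitulated_b_in_a"] = _fraction_recapitulated(
            hmrs_by_context[ctx_b], hmrs_by_context[ctx_a]
        )
        scatter = pd.DataFrame(
            [
                (
                    h.interval.name,
                    h.label,
                    h.reads_by_sample["A"],
                    h.reads_by_sample["B_normalized"],
                    h.fold,
                )
                for h in classified
            ],
            columns=["hmr", "label", "n_a", "n_b_normalized", "fold"],
        )
        scatter.to_csv(outdir / "biocap_scatter.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError("classify", exc) from exc

    # ---- sequence features + repeat ages -------------------------------
    try:
        _stage("profile")
        seq = bundle.sequences[config.sim.transplant_contig]
        feature_rows = []
        for h in classified:
            sub = seq[h.interval.start : h.interval.end]
            feature_rows.append(
                (
                    h.interval.name,
                    h.label,
                    h.interval.length,
                    fp.cpg_density(sub),
                    fp.gc_content(sub),
                )
            )
        features = pd.DataFrame(
            feature_rows,
            columns=["hmr", "label", "length", "cpg_per_100bp", "gc_fraction"],
        )
        features.to_csv(outdir / "hmr_features.tsv", sep="\t", index=False)
        if classified:
            background = fp.shifted_background(
                [h.interval for h in classified],
                len(seq),
                excluded=[h.interval for h in classified],
                seed=config.seed + _SEED_SHIFT,
            )
            bg_density = [
                fp.cpg_density(seq[iv.start : iv.end]) for iv in background
            ]
            report["mean_cpg_density_hmr"] = float(features["cpg_per_100bp"].mean())
            report["mean_cpg_density_background"] = float(np.mean(bg_density))
        ages = fp.summit_repeat_ages(classified, bundle.repeat_truth, config.repeat_age)
        age_rows = [
            (label, age) for label, arr in sorted(ages.items()) for age in arr
        ]
        pd.DataFrame(age_rows, columns=["label", "age_years"]).to_csv(
            outdir / "repeat_ages.tsv", sep="\t", index=False
        )
        if "shared" in ages and "B_specific" in ages:
            u, p = fp.compare_age_groups(ages, "shared", "B_specific")
            report["repeat_age_mannwhitney"] = {"U": u, "p": p}
    except Exception as exc:
        raise StageError("profile", exc) from exc

    # ---- TSS / TF annotation -------------------------------------------
    try:
        _stage("annotate")
        associated, distal = oa.classify_tss_proximity(
            classified, bundle.tss_truth, config.annotation
        )
        report["tss_associated_fraction"] = (
            len(associated) / len(classified) if classified else None
        )
        tf_split = oa.species_specific_peaks(
            bundle.tf_truth_by_context[ctx_a], bundle.tf_truth_by_context[ctx_b]
        )
        tf_overlap = {}
        for label, key in (("A_specific", "a_specific"), ("B_specific", "b_specific")):
            ss = [h for h in classified if h.label == label]
            if not ss:
                tf_overlap[label] = None
                continue
            by_factor = {}
            for p in tf_split[key]:
                by_factor.setdefault(p.factor, []).append(p)
            summary = oa.multiway_overlap_summary(ss, by_factor)
            tf_overlap[label] = {
                "n_targets": summary["n_targets"],
                "n_overlapping": summary["n_overlapping"],
                "percent_overlapping": summary["percent_overlapping"],
            }
        report["ss_hmr_tf_overlap"] = tf_overlap
        if classified:
            matrix, ranked, metaplot = oa.aggregate_matrix(
                classified, cov[ctx_a], flank=5000, bins=50
            )
            pd.DataFrame(
                matrix,
                index=[iv.name for iv in ranked],
            ).to_csv(outdir / "signal_matrix.tsv", sep="\t")
            pd.DataFrame({"bin": range(len(metaplot)), "mean": metaplot}).to_csv(
                outdir / "metaplot.tsv", sep="\t", index=False
            )
    except Exception as exc:
        raise StageError("annotate", exc) from exc

    # ---- bisulfite validation ------------------------------------------
    try:
        _stage("bisulfite")
        amplicons = [
            el.interval
            for el in bundle.planted_elements
            if el.hypomethylated_in != "shared"
        ][:10]
        if amplicons:
            bs_report = {}
            mean_by_context = {}
            for ctx in (ctx_a, ctx_b):
                calls, spike_u, spike_m = sd.simulate_bisulfite_counts(
                    bundle,
                    ctx,
                    amplicons,
                    seed=config.seed + _SEED_BISULFITE[ctx],
                )
                iof.save_methcalls(calls, outdir / f"bisulfite_{ctx}.tsv")
                summaries = [bs.summarize_amplicon(a, calls) for a in amplicons]
                mean_by_context[ctx] = {
                    a.name or f"{a.start}": s.mean_percent
                    for a, s in zip(amplicons, summaries)
                }
                qc = bs.conversion_efficiency(spike_u, spike_m)
                bs_report[ctx] = {
                    "conversion": qc["conversion"],
                    "overconversion_proxy": qc["overconversion_proxy"],
                    "qc_pass": qc["qc_pass"],
                }
            report["bisulfite_qc"] = bs_report
            report["bisulfite_mean_percent"] = mean_by_context
    except Exception as exc:
        raise StageError("bisulfite", exc) from exc

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    log.info("report written to %s", report_path)
    return report
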