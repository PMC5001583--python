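import numpy as np
import pytest
from scipy import stats

from hmr_transplant.hmr_detection import Hmr
from hmr_transplant.io_formats import CoverageTrack, GenomicInterval
from hmr_transplant.overlap_annotation import (
    AnnotationParams,
    TfPeak,
    aggregate_matrix,
    classify_tss_proximity,
    fold_change_by_location,
    multiway_overlap_summary,
    species_specific_peaks,
)

from .oracles import welch_t


def _hmr(start, end, label="unclassified", fold=None):
    return Hmr(
        interval=GenomicInterval("chrT", start, end),
        summit=start,
        p_value=1e-9,
        label=label,
        fold=fold,
    )


def _tss(pos, strand="+"):
    return GenomicInterval("chrT", pos, pos + 1, strand=strand)


class TestTssProximity:
    def test_window_edge_overlap_is_associated(self):
        assoc, distal = classify_tss_proximity(
            [_hmr(900, 1100)], [_tss(1500)], AnnotationParams(tss_window=500)
        )
        assert len(assoc) == 1 and distal == []

    def test_far_hmr_is_distal(self):
        assoc, distal = classify_tss_proximity(
            [_hmr(0, 400)], [_tss(1000)], AnnotationParams(tss_window=500)
        )
        assert assoc == [] and len(distal) == 1

    def test_zero_window_is_single_position(self):
        assoc, _ = classify_tss_proximity(
            [_hmr(999, 1001)], [_tss(1000)], AnnotationParams(tss_window=0)
        )
        assert len(assoc) == 1

    def test_strand_does_not_alter_window(self):
        for strand in "+-":
            assoc, _ = classify_tss_proximity(
                [_hmr(900, 1100)], [_tss(1500, strand)], AnnotationParams(500)
            )
            assert len(assoc) == 1

    def test_partition(self):
        hmrs = [_hmr(i * 3000, i * 3000 + 500) for i in range(20)]
        assoc, distal = classify_tss_proximity(hmrs, [_tss(3100), _tss(40_000)])
        assert len(assoc) + len(distal) == len(hmrs)
        assert not (set(map(id, assoc)) & set(map(id, distal)))


def _tf(start, end, factor, context):
    return TfPeak(GenomicInterval("chrT", start, end), factor, context)


class TestSpeciesSpecificPeaks:
    def test_identical_sets_all_shared(self):
        a = [_tf(0, 100, "CEBPA", "A"), _tf(500, 600, "CTCF", "A")]
        b = [_tf(0, 100, "CEBPA", "B"), _tf(500, 600, "CTCF", "B")]
        split = species_specific_peaks(a, b)
        assert split["a_specific"] == [] and split["b_specific"] == []
        assert len(split["shared"]) == 4

    def test_disjoint_sets_all_specific(self):
        a = [_tf(0, 100, "CEBPA", "A")]
        b = [_tf(5000, 5100, "CEBPA", "B")]
        split = species_specific_peaks(a, b)
        assert split["a_specific"] == a and split["b_specific"] == b

    def test_factor_stratified_intersection(self):
        a = [_tf(0, 100, "CEBPA", "A")]
        b = [_tf(0, 100, "HNF4A", "B")]  # same span, different factor
        split = species_specific_peaks(a, b)
        assert split["a_specific"] == a and split["b_specific"] == b

    def test_partition_per_context(self):
        a = [_tf(i * 300, i * 300 + 100, "CTCF", "A") for i in range(10)]
        b = [_tf(i * 700, i * 700 + 100, "CTCF", "B") for i in range(5)]
        split = species_specific_peaks(a, b)
        shared_a = [p for p in split["shared"] if p.context == "A"]
        assert len(split["a_specific"]) + len(shared_a) == len(a)


class TestMultiwayOverlap:
    def test_no_features_gives_zero_percent(self):
        targets = [_hmr(i * 1000, i * 1000 + 100) for i in range(5)]
        summary = multiway_overlap_summary(targets, {"CEBPA": [], "CTCF": []})
        assert summary["percent_overlapping"] == 0

    def test_total_overlap_gives_single_pattern(self):
        targets = [_hmr(i * 1000, i * 1000 + 100) for i in range(4)]
        blanket = [GenomicInterval("chrT", 0, 10_000)]
        summary = multiway_overlap_summary(
            targets, {"s1": blanket, "s2": blanket}
        )
        assert summary["percent_overlapping"] == 100
        assert summary["pattern_counts"] == {(True, True): 4}

    def test_pattern_counts_sum_to_targets(self):
        rng = np.random.default_rng(2)
        targets = [_hmr(i * 1000, i * 1000 + 200) for i in range(30)]
        feats = {
            "x": [GenomicInterval("chrT", int(s), int(s) + 300) for s in rng.integers(0, 30_000, 8)],
            "y": [GenomicInterval("chrT", int(s), int(s) + 300) for s in rng.integers(0, 30_000, 8)],
        }
        summary = multiway_overlap_summary(targets, feats)
        assert sum(summary["pattern_counts"].values()) == 30

    def test_empty_target_list_rejected(self):
        with pytest.raises(ValueError):
            multiway_overlap_summary([], {"x": []})

    def test_more_than_four_sets_rejected(self):
        with pytest.raises(ValueError):
            multiway_overlap_summary(
                [_hmr(0, 10)], {str(i): [] for i in range(5)}
            )


class TestAggregateMatrix:
    def test_flat_coverage_fills_matrix(self):
        cov = CoverageTrack("chrT", np.full(10_000, 5.0), total_reads=100.0)
        matrix, _, metaplot = aggregate_matrix(
            [_hmr(4000, 4500), _hmr(6000, 6200)], cov, flank=500, bins=10
        )
        assert np.all(matrix == 5.0)
        assert np.all(metaplot == 5.0)

    def test_zero_coverage_gives_zero_matrix(self):
        cov = CoverageTrack("chrT", np.zeros(10_000), total_reads=1.0)
        matrix, _, _ = aggregate_matrix([_hmr(5000, 5400)], cov, flank=400, bins=8)
        assert not np.nansum(matrix)

    def test_triangular_peak_maximal_at_center(self):
        values = np.zeros(10_000)
        mid = 5000
        width = 800
        ramp = np.concatenate([np.linspace(0, 1, width), np.linspace(1, 0, width)])
        values[mid - width : mid + width] = ramp
        cov = CoverageTrack("chrT", values, total_reads=10.0)
        matrix, _, metaplot = aggregate_matrix(
            [_hmr(mid - 200, mid + 200)], cov, flank=1000, bins=20
        )
        center_bins = metaplot[9:11]
        assert np.nanmax(metaplot) == pytest.approx(np.max(center_bins))

    def test_rows_ranked_by_length_descending(self):
        cov = CoverageTrack("chrT", np.ones(50_000), total_reads=10.0)
        hmrs = [_hmr(1000, 1200), _hmr(9000, 9900), _hmr(20_000, 20_500)]
        _, ranked, _ = aggregate_matrix(hmrs, cov, flank=100, bins=4)
        assert [iv.length for iv in ranked] == [900, 500, 200]

    def test_contig_edge_padded_with_nan(self):
        cov = CoverageTrack("chrT", np.ones(2000), total_reads=10.0)
        matrix, _, _ = aggregate_matrix([_hmr(0, 200)], cov, flank=500, bins=10)
        assert np.isnan(matrix[0, 0]) and matrix[0, -1] == 1.0


class TestFoldChangeByLocation:
    def test_identical_groups_t_zero_p_one(self):
        tss = [_hmr(0, 100, fold=f) for f in (2.0, 3.0, 4.0)]
        distal = [_hmr(1000 + i, 1100 + i, fold=f) for i, f in enumerate((2.0, 3.0, 4.0))]
        result = fold_change_by_location(tss + distal, tss_associated=tss)
        assert result["t_statistic"] == pytest.approx(0.0)
        assert result["p_value"] == pytest.approx(1.0)

    def test_matches_hand_welch_formula(self):
        tss = [_hmr(0, 100, fold=f) for f in (1.0, 2.0, 3.0)]
        distal = [_hmr(1000 + i, 1100 + i, fold=f) for i, f in enumerate((2.0, 3.0, 4.0))]
        result = fold_change_by_location(tss + distal, tss_associated=tss)
        t_ref, df_ref = welch_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert result["t_statistic"] == pytest.approx(t_ref, rel=1e-12)
        assert result["p_value"] == pytest.approx(
            2 * stats.t.sf(abs(t_ref), df_ref), rel=1e-9
        )

    def test_fold_magnitude_symmetrizes_directions(self):
        # fold 0.25 (B-specific) and fold 4.0 (A-specific) are the same magnitude
        tss = [_hmr(0, 100, fold=0.25), _hmr(200, 300, fold=4.0)]
        distal = [_hmr(1000, 1100, fold=2.0), _hmr(2000, 2100, fold=3.0)]
        result = fold_change_by_location(tss + distal, tss_associated=tss)
        assert list(result["tss_folds"]) == [4.0, 4.0]
        assert result["t_statistic"] == pytest.approx(
            welch_t([4.0, 4.0], [2.0, 3.0])[0]
        )

    def test_degenerate_variance_rejected(self):
        tss = [_hmr(0, 100, fold=2.0), _hmr(200, 300, fold=2.0)]
        distal = [_hmr(1000, 1100, fold=2.0), _hmr(2000, 2100, fold=2.0)]
        with pytest.raises(ValueError, match="degenerate"):
            fold_change_by_location(tss + distal, tss_associated=tss)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            fold_change_by_location([_hmr(0, 100, fold=2.0)], tss_associated=[])
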