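import numpy as np
import pytest

import hmr_transplant as ht
from hmr_transplant.io_formats import GenomicInterval, cpg_positions
from hmr_transplant.synthetic_data import SimulationSizeError

SMALL = dict(
    transplant_length=200_000,
    host_length=20_000,
    n_shared_cgis=8,
    n_a_specific=4,
    n_b_specific=4,
    n_young_repeats=4,
    n_tf_sites_per_context=4,
)


class TestGenomeGeneration:
    def test_same_seed_is_byte_identical(self):
        b1 = ht.simulate_composite_genome(ht.SimConfig(seed=7, **SMALL))
        b2 = ht.simulate_composite_genome(ht.SimConfig(seed=7, **SMALL))
        assert b1.sequences == b2.sequences
        for ctx in ("A", "B"):
            for contig in b1.sequences:
                p1, m1 = b1.methylome_by_context[ctx].levels[contig]
                p2, m2 = b2.methylome_by_context[ctx].levels[contig]
                assert np.array_equal(p1, p2) and np.array_equal(m1, m2)

    def test_nothing_planted_gives_background_methylome(self):
        cfg = ht.SimConfig(
            seed=3,
            transplant_length=100_000,
            n_shared_cgis=0,
            n_a_specific=0,
            n_b_specific=0,
            n_young_repeats=0,
            n_tf_sites_per_context=0,
        )
        bundle = ht.simulate_composite_genome(cfg)
        assert bundle.cgi_truth == []
        for ctx in ("A", "B"):
            m = bundle.methylome_by_context[ctx].values("chrT")
            # Beta(8.5, 1.5) has mean 0.85
            assert abs(m.mean() - 0.85) < 0.02

    def test_cgi_cpg_density_above_length_matched_background(self, default_bundle):
        """Oracle: direct CG-dinucleotide counts in CGIs vs random windows."""
        seq = default_bundle.sequences["chrT"]
        occupied = np.zeros(len(seq), dtype=bool)
        for el in default_bundle.planted_elements:
            occupied[el.interval.start : el.interval.end] = True

        def density(start, end):
            return cpg_positions(seq[start:end]).size / (end - start)

        cgi = [density(iv.start, iv.end) for iv in default_bundle.cgi_truth]
        rng = np.random.default_rng(0)
        background = []
        for iv in default_bundle.cgi_truth:
            while True:
                s = int(rng.integers(0, len(seq) - iv.length))
                if not occupied[s : s + iv.length].any():
                    background.append(density(s, s + iv.length))
                    break
        assert np.mean(cgi) > np.mean(background)

    def test_truth_sets_within_contig_and_non_overlapping(self, default_bundle):
        L = len(default_bundle.sequences["chrT"])
        ivs = sorted(
            (el.interval for el in default_bundle.planted_elements),
            key=lambda iv: iv.start,
        )
        assert all(0 <= iv.start < iv.end <= L for iv in ivs)
        assert all(a.end <= b.start for a, b in zip(ivs, ivs[1:]))

    def test_young_repeats_have_low_millidiv(self, default_bundle):
        young = [r for r in default_bundle.repeat_truth if r.family == "AluYsim"]
        old = [r for r in default_bundle.repeat_truth if r.family == "L2sim"]
        assert young and old
        assert max(r.milli_div for r in young) <= 50
        assert min(r.milli_div for r in old) >= 150

    def test_footprint_overflow_names_counts(self):
        cfg = ht.SimConfig(seed=0, transplant_length=30_000, n_shared_cgis=50)
        with pytest.raises(SimulationSizeError, match="n_shared_cgis=50"):
            ht.simulate_composite_genome(cfg)


class TestBiocapCoverage:
    def test_fully_methylated_gives_uniform_background(self):
        cfg = ht.SimConfig(seed=5, **SMALL)
        bundle = ht.simulate_composite_genome(cfg)
        for ctx in ("A", "B"):
            for contig, (pos, m) in bundle.methylome_by_context[ctx].levels.items():
                m[:] = 1.0  # no unmethylated CpGs anywhere
        cov = ht.simulate_biocap_coverage(bundle, "A", replicate_seed=1, depth=30)
        binned = cov.values[: 200_000].reshape(20, -1).mean(axis=1)
        assert np.all(np.abs(binned / binned.mean() - 1) < 0.1)

    def test_single_cgi_zero_background_captures_everything(self):
        cfg = ht.SimConfig(
            seed=2,
            transplant_length=50_000,
            host_length=5_000,
            n_shared_cgis=1,
            n_a_specific=0,
            n_b_specific=0,
            n_young_repeats=0,
            n_tf_sites_per_context=0,
            biocap_background_rate=0.0,
            fragment_len_sd=0.0,
        )
        bundle = ht.simulate_composite_genome(cfg)
        pos, m = bundle.methylome_by_context["A"].levels["chrT"]
        (cgi,) = bundle.cgi_truth
        outside = (pos < cgi.start) | (pos >= cgi.end)
        m[outside] = 1.0  # kill residual background capture weight
        cov = ht.simulate_biocap_coverage(bundle, "A", replicate_seed=9, depth=5)
        covered = np.flatnonzero(cov.values)
        frag = int(cfg.fragment_len_mean)
        assert covered.min() >= cgi.start - frag
        assert covered.max() <= cgi.end + frag

    def test_capture_monotone_in_unmethylated_cpg_count(self, default_bundle):
        """A CpG-rich unmethylated element accumulates more coverage than an
        intermediate-CpG one of similar size, at matched methylation state."""
        cov = ht.simulate_biocap_coverage(default_bundle, "A", replicate_seed=4)
        rich = [
            el.interval
            for el in default_bundle.planted_elements
            if el.hypomethylated_in == "A" and el.mechanism == "young_repeat"
        ]
        poor = [
            el.interval
            for el in default_bundle.planted_elements
            if el.hypomethylated_in == "A" and el.mechanism == "tf_protected"
        ]
        mean_rich = np.mean([cov.values[iv.start : iv.end].mean() for iv in rich])
        mean_poor = np.mean([cov.values[iv.start : iv.end].mean() for iv in poor])
        assert mean_rich > mean_poor

    def test_fragment_conservation(self):
        cfg = ht.SimConfig(seed=8, fragment_len_sd=0.0, **SMALL)
        bundle = ht.simulate_composite_genome(cfg)
        cov = ht.simulate_biocap_coverage(bundle, "A", replicate_seed=1, depth=10)
        n_expected = round(10 * cfg.transplant_length / cfg.fragment_len_mean)
        assert cov.total_reads == n_expected
        # with fixed-length fragments, coverage mass = fragments x length
        assert cov.values.sum() == pytest.approx(
            n_expected * cfg.fragment_len_mean, rel=1e-12
        )

    def test_depth_must_be_positive(self, default_bundle):
        with pytest.raises(ValueError, match="depth"):
            ht.simulate_biocap_coverage(default_bundle, "A", replicate_seed=1, depth=0)


class TestInputControl:
    def test_zero_depth_gives_empty_track(self, default_bundle):
        track = ht.simulate_input_control(default_bundle, seed=1, depth=0)
        assert track.total_reads == 0 and not track.values.any()

    def test_mean_close_to_depth(self, default_bundle):
        track = ht.simulate_input_control(default_bundle, seed=1, depth=20)
        assert abs(track.values.mean() / 20 - 1) < 0.05

    def test_same_seed_identical(self, default_bundle):
        t1 = ht.simulate_input_control(default_bundle, seed=6, depth=5)
        t2 = ht.simulate_input_control(default_bundle, seed=6, depth=5)
        assert np.array_equal(t1.values, t2.values)


@pytest.fixture(scope="module")
def small_bundle():
    return ht.simulate_composite_genome(ht.SimConfig(seed=4, **SMALL))


class TestBisulfiteSimulation:
    def test_perfect_conversion_of_unmethylated(self, small_bundle):
        amp = small_bundle.cgi_truth[0]  # hypomethylated in both contexts
        pos, m = small_bundle.methylome_by_context["A"].levels["chrT"]
        lo, hi = np.searchsorted(pos, (amp.start, amp.end))
        m[lo:hi] = 0.0
        calls, _, _ = ht.simulate_bisulfite_counts(
            small_bundle, "A", [amp], depth=40, conversion_rate=1.0, seed=1
        )
        assert calls and all(c.meth_count == 0 for c in calls)

    def test_fully_methylated_ignores_conversion_rate(self, small_bundle):
        amp = small_bundle.cgi_truth[1]
        pos, m = small_bundle.methylome_by_context["A"].levels["chrT"]
        lo, hi = np.searchsorted(pos, (amp.start, amp.end))
        m[lo:hi] = 1.0
        calls, _, _ = ht.simulate_bisulfite_counts(
            small_bundle, "A", [amp], depth=40, conversion_rate=0.9, seed=1
        )
        assert calls and all(c.meth_count == 40 for c in calls)

    def test_incomplete_conversion_binomial_expectation(self, small_bundle):
        """m = 0, conversion 0.99: observed methylation ~ 1% within
        binomial error (oracle: p_obs = 0.01)."""
        amp = small_bundle.cgi_truth[2]
        pos, m = small_bundle.methylome_by_context["A"].levels["chrT"]
        lo, hi = np.searchsorted(pos, (amp.start, amp.end))
        m[lo:hi] = 0.0
        n_cpgs = hi - lo
        calls, _, _ = ht.simulate_bisulfite_counts(
            small_bundle, "A", [amp], depth=1000, conversion_rate=0.99, seed=1
        )
        frac = sum(c.meth_count for c in calls) / sum(c.depth for c in calls)
        se = np.sqrt(0.01 * 0.99 / (1000 * n_cpgs))
        assert abs(frac - 0.01) < 4 * se

    def test_amplicon_without_cpg_warns_and_is_empty(self, small_bundle):
        seq = small_bundle.sequences["chrT"]
        pos = cpg_positions(seq)
        # find a CpG-free gap of >= 30 bp
        gaps = np.diff(pos)
        i = int(np.argmax(gaps))
        start = int(pos[i]) + 2
        amp = GenomicInterval("chrT", start, start + 20)
        with pytest.warns(UserWarning, match="no CpG"):
            calls, _, _ = ht.simulate_bisulfite_counts(
                small_bundle, "A", [amp], depth=10, seed=1
            )
        assert calls == []

    def test_spikeins_are_pure_controls(self, small_bundle):
        _, spike_u, spike_m = ht.simulate_bisulfite_counts(
            small_bundle, "A", [], depth=100, conversion_rate=1.0, seed=1
        )
        assert spike_u and spike_m
        assert all(c.meth_count == 0 for c in spike_u)
        assert all(c.meth_count == 100 for c in spike_m)
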