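"""Shared fixtures: one default simulated experiment reused across modules.

The heavy objects (composite genome, replicate coverage tracks, two-context
HMR calls) are session-scoped so the whole suite simulates the default study
conditions exactly once.
"""

import numpy as np
import pytest

import hmr_transplant as ht
from hmr_transplant.io_formats import CoverageTrack


@pytest.fixture(scope="session")
def default_bundle():
    """Default study conditions: 2 Mb donor contig, 60 shared CGIs,
    20 context-specific elements per host, seed 1."""
    return ht.simulate_composite_genome(ht.SimConfig(seed=1))


@pytest.fixture(scope="session")
def replicates_a(default_bundle):
    """Two independent BioCAP replicates of context A (seeds 1 and 2, 30x)."""
    rep1 = ht.simulate_biocap_coverage(default_bundle, "A", replicate_seed=1, depth=30)
    rep2 = ht.simulate_biocap_coverage(default_bundle, "A", replicate_seed=2, depth=30)
    return rep1, rep2


@pytest.fixture(scope="session")
def replicates_b(default_bundle):
    rep1 = ht.simulate_biocap_coverage(default_bundle, "B", replicate_seed=3, depth=30)
    rep2 = ht.simulate_biocap_coverage(default_bundle, "B", replicate_seed=4, depth=30)
    return rep1, rep2


@pytest.fixture(scope="session")
def input_controls(default_bundle):
    ctrl_a = ht.simulate_input_control(default_bundle, seed=31)
    ctrl_b = ht.simulate_input_control(default_bundle, seed=32)
    return ctrl_a, ctrl_b


def _pool(tracks):
    return CoverageTrack(
        contig=tracks[0].contig,
        values=tracks[0].values + tracks[1].values,
        total_reads=tracks[0].total_reads + tracks[1].total_reads,
    )


@pytest.fixture(scope="session")
def two_context_hmrs(default_bundle, replicates_a, replicates_b, input_controls):
    """Replicate-reproducible HMRs per context plus the classified union."""
    ctrl_a, ctrl_b = input_controls
    peaks_a = [ht.call_peaks(t, ctrl_a) for t in replicates_a]
    peaks_b = [ht.call_peaks(t, ctrl_b) for t in replicates_b]
    hmrs_a = ht.intersect_replicates(*peaks_a)
    hmrs_b = ht.intersect_replicates(*peaks_b)
    union = ht.merge_union(hmrs_a, hmrs_b)
    classified = ht.classify_hmrs(union, _pool(replicates_a), _pool(replicates_b))
    return {"A": hmrs_a, "B": hmrs_b, "classified": classified}
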