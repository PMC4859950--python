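"""Shared fixtures: simulated communities and pipeline runs reused across
test modules (session-scoped because the full pipeline is the expensive
part of the suite)."""

from __future__ import annotations

import pytest

from focuslite import (CommunityConfig, run_pipeline,
                       sample_reads, simulate_community, truth_annotations)
from focuslite.simdata import PRESETS


@pytest.fixture(scope="session")
def small_community():
    """Two genomes sharing a 500 bp element; quick pipeline run."""
    cfg = PRESETS["small"]
    genomes, truth = simulate_community(cfg)
    reads, truth = sample_reads(genomes, cfg, truth)
    result = run_pipeline(reads)
    return cfg, genomes, truth, reads, result


@pytest.fixture(scope="session")
def planted_community():
    """The headline study condition: three 20 kb genomes sharing a 1 kb
    transposase-like element, 20x error-free coverage."""
    cfg = PRESETS["shared-transposon"]
    genomes, truth = simulate_community(cfg)
    reads, truth = sample_reads(genomes, cfg, truth)
    result = run_pipeline(reads)
    return cfg, genomes, truth, reads, result


@pytest.fixture(scope="session")
def planted_annotations(planted_community):
    cfg, genomes, truth, reads, result = planted_community
    live = {
        k: n.member_reads
        for k, n in result.hybrid.nodes.items() if k in result.hybrid.hybrid
    }
    return truth_annotations(truth, live)


@pytest.fixture(scope="session")
def grouped_community():
    """Six genomes, two carrier groups ({0,1,2} and {3,4,5}) each sharing a
    distinct element, for phylogenetic-cluster recovery tests."""
    cfg = CommunityConfig(
        n_genomes=6, genome_len=10_000, transposon_len=900, ir_len=30,
        transposon_carriers=((0, 1, 2), (3, 4, 5)), rrna_copies=1,
        rrna_len=300, resistance_offset=800, resistance_len=300,
        background_genes_per_genome=3, background_len=250,
        coverage=10.0, seed=7,
    )
    genomes, truth = simulate_community(cfg)
    reads, truth = sample_reads(genomes, cfg, truth)
    result = run_pipeline(reads)
    return cfg, genomes, truth, reads, result
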