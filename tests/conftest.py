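"""Shared fixtures: a small oracle-scale community and the default-scale
study community run once through the pipeline for the end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

from ptscope import community, ptseq

STUDY_SEED = 11


@pytest.fixture(scope="session")
def small_community():
    """Oracle-scale community (<= 50 kb total) for brute-force comparisons."""
    return community.build_community(
        n_genomes=3,
        genome_length=15_000,
        pt_genome_fraction=0.67,
        seed=202,
        read_length=80,
    )


@pytest.fixture(scope="session")
def small_alignments(small_community):
    reads = community.simulate_ptseq_reads(
        small_community,
        n_reads=8_000,
        read_length=80,
        background_nick_rate=0.3,
        seed=203,
    )
    return ptseq.assign_reads(reads, small_community)


@pytest.fixture(scope="session")
def study_community():
    """The default study conditions: 20 genomes of 200 kb, 2 PT carriers
    (single-strand C*AG and bistranded G*AAC/G*TTC) at occupancy 0.125."""
    return community.build_community(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_reads(study_community):
    return community.simulate_ptseq_reads(study_community, seed=STUDY_SEED + 1)


@pytest.fixture(scope="session")
def study_pipeline(study_community, study_reads):
    """Full pipeline run at default parameters; reused across tests."""
    com = study_community
    aln = ptseq.assign_reads(study_reads, com)
    stats_list = [ptseq.genome_stats(aln, g.genome_id, g.length) for g in com.genomes]
    labels, model = ptseq.gmm_cluster(
        ptseq.genome_features(stats_list), seed=STUDY_SEED + 2
    )
    selected = ptseq.select_candidate_genomes(stats_list, labels)
    seqs = {g.genome_id: g.sequence for g in com.genomes}
    called = {
        gid: ptseq.call_pileups(aln, gid, seqs[gid], cutoff=ptseq.DEFAULT_CUTOFF)
        for gid in sorted(selected)
    }
    return {
        "community": com,
        "alignments": aln,
        "stats": stats_list,
        "labels": labels,
        "selected": selected,
        "called": called,
        "sequences": seqs,
    }
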