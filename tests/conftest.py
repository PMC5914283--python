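"""Shared fixtures: synthetic reference databases generated at test time."""

from __future__ import annotations

import pytest

from amplieval.pcr import DEFAULT_PRIMER_PAIRS, extract_region
from amplieval.simulate import SimConfig, generate_reference


@pytest.fixture(scope="session")
def small_db():
    """A 3-cluster, 15-record database at the generator defaults."""
    return generate_reference(SimConfig(n_clusters=3, seqs_per_cluster=5, seed=1))


@pytest.fixture(scope="session")
def eval_db():
    """A 12-cluster, 60-record database built for clustering evaluation.

    Tighter within-cluster divergence than the default gives a comfortable
    margin around the 0.97 identity threshold; the separation is verified
    against an independent edit-distance oracle where tests rely on it.
    """
    config = SimConfig(
        n_clusters=12,
        seqs_per_cluster=5,
        within_cluster_sub_rate=0.006,
        between_cluster_divergence=0.12,
        seed=11,
    )
    return generate_reference(config)


@pytest.fixture(scope="session")
def eval_truth(eval_db):
    return {rec.id: rec.truth_cluster for rec in eval_db}


@pytest.fixture(scope="session")
def region_extracts(eval_db):
    """Region name -> {record id -> error-free amplicon sequence}."""
    out = {}
    for region, pair in DEFAULT_PRIMER_PAIRS.items():
        out[region] = {
            rec.id: extract_region(rec, pair).sequence for rec in eval_db
        }
    return out
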