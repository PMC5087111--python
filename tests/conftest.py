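from __future__ import annotations

import pytest
from hypothesis import settings

import sagscope as s

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_refset() -> s.ReferenceSet:
    """Two symbiont genomes, 8 kb each, 6 CDS per genome."""
    return s.generate_references(2, 8000, 6, hk_fraction=0.4, seed=11)


@pytest.fixture(scope="session")
def community():
    """Error-free community: 4 symbionts + host, 10^4 fragments, aligned.

    Session-scoped because the acceptance-grade retrieval checks and several
    unit tests reuse it (building it once keeps the suite fast).
    """
    refset, targets = s.generate_community(
        n_symbionts=4, contig_length=20_000, n_cds_per_genome=20, seed=101
    )
    weights = s.sample_expression(refset, lognormal_sigma=1.0, seed=102)
    frags = s.simulate_fragments(
        refset, weights, 10_000, insert_mean=149.0, insert_sd=30.0, seed=103
    )
    index = s.build_index(refset, 21)
    pairs = [(f.fragment_id, f.mate1_seq, f.mate2_seq) for f in frags]
    assignments = s.assign_pairs(pairs, index, s.AssignParams())
    truth = {f.fragment_id: f.genome_id for f in frags}
    return dict(
        refset=refset,
        targets=targets,
        weights=weights,
        fragments=frags,
        index=index,
        pairs=pairs,
        assignments=assignments,
        truth=truth,
    )
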