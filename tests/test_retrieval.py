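"""Seed-and-extend pair assignment and retrieval evaluation."""

from __future__ import annotations

import numpy as np
import pytest

import sagscope as s
from sagscope.align import STATUS_MULTI, STATUS_OUT_OF_BOUNDS, STATUS_UNIQUE
from _oracles import oracle_assign_pair


def _single_contig_refset(seq: str, genome_id: str = "g1") -> s.ReferenceSet:
    return s.ReferenceSet(
        genomes=[s.Genome(genome_id, {f"{genome_id}_c0": seq})]
    )


class TestSeedIndex:
    def test_indexed_position_count(self):
        rs = _single_contig_refset("ACGTACGT")
        idx = s.build_index(rs, 4)
        assert idx.n_positions() == 5  # 8 - 4 + 1 k-mer start positions

    def test_absent_kmer_gives_empty_posting_list(self):
        rs = _single_contig_refset("ACGTACGT")
        idx = s.build_index(rs, 4)
        assert idx.lookup("GGGG") == []

    def test_independent_of_contig_insertion_order(self):
        g1 = s.Genome("g1", {"c1": "ACGTACGTACGT", "c2": "TTTTGGGGCCCC"})
        g1r = s.Genome("g1", {"c2": "TTTTGGGGCCCC", "c1": "ACGTACGTACGT"})
        i1 = s.build_index(s.ReferenceSet(genomes=[g1]), 4)
        i2 = s.build_index(s.ReferenceSet(genomes=[g1r]), 4)
        assert i1._table == i2._table


class TestAssignPair:
    def test_planted_pair_recovered_at_true_locus(self, community):
        # error-free, k-mer-disjoint genomes: every pair lands uniquely
        # exactly where the simulator put it
        truth_by_id = {f.fragment_id: f for f in community["fragments"]}
        for a in community["assignments"][:500]:
            f = truth_by_id[a.fragment_id]
            assert a.status == STATUS_UNIQUE
            assert a.genome_id == f.genome_id
            assert (a.mate1_start, a.mate1_end) == f.mate1_interval
            assert (a.mate2_start, a.mate2_end) == f.mate2_interval
            assert a.fragment_length == f.insert_size

    def test_fragment_length_bound_is_inclusive(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 1200))
        rs = _single_contig_refset(seq)
        idx = s.build_index(rs, 21)
        read_len = 101
        for frag, expect in [(450, STATUS_UNIQUE), (451, STATUS_OUT_OF_BOUNDS)]:
            m1 = seq[100 : 100 + read_len]
            m2 = s.reverse_complement(seq[100 + frag - read_len : 100 + frag])
            a = s.assign_pair(("p", m1, m2), idx, s.AssignParams(max_frag=450))
            assert a.status == expect, frag

    def test_duplicated_reference_makes_pairs_multi(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        rs = s.ReferenceSet(
            genomes=[s.Genome("gA", {"cA": seq}), s.Genome("gA2", {"cA2": seq})]
        )
        idx = s.build_index(rs, 21)
        m1 = seq[300:401]
        m2 = s.reverse_complement(seq[350:451])
        a = s.assign_pair(("p", m1, m2), idx, s.AssignParams())
        assert a.status == STATUS_MULTI

    @pytest.mark.parametrize("error_rate", [0.0, 0.02])
    def test_agrees_with_all_positions_oracle(self, error_rate):
        # <= 2 kb total reference: exhaustive oracle is affordable
        rs = s.generate_references(
            2, 900, 2, cds_length_range=(150, 300), seed=21
        )
        w = s.sample_expression(rs, seed=22)
        frags = s.simulate_fragments(
            rs, w, 60, read_len=50, insert_mean=120, insert_sd=20,
            error_rate=error_rate, seed=23,
        )
        idx = s.build_index(rs, 12)
        params = s.AssignParams(seed_k=12, max_mismatch=2, min_frag=20, max_frag=450)
        for f in frags:
            pair = (f.fragment_id, f.mate1_seq, f.mate2_seq)
            got = s.assign_pair(pair, idx, params)
            want_status, want_best = oracle_assign_pair(pair, rs, params)
            assert got.status == want_status
            if want_status == STATUS_UNIQUE:
                _, cid, st1, sd1, st2, frag_len = want_best
                assert (got.contig_id, got.mate1_start, got.strand) == (cid, st1, sd1)
                assert got.fragment_length == frag_len


class TestEvaluate:
    def test_perfect_assignment_gives_unit_metrics(self, community):
        m = s.evaluate_retrieval(
            community["assignments"], community["truth"], community["targets"]
        )
        assert (m.per_genome["precision"] == 1.0).all()
        assert (m.per_genome["recall"] == 1.0).all()

    def test_confusion_counts_conserve_input_pairs(self, community):
        m = s.evaluate_retrieval(community["assignments"], community["truth"])
        assert m.n_pairs == len(community["assignments"])

    def test_duplicated_genomes_recall_zero_precision_one(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 3000))
        rs = s.ReferenceSet(
            genomes=[s.Genome("gA", {"cA": seq}), s.Genome("gB", {"cB": seq})]
        )
        idx = s.build_index(rs, 21)
        pairs, truth = [], {}
        for i in range(30):
            start = 40 * i
            m1 = seq[start : start + 101]
            m2 = s.reverse_complement(seq[start + 48 : start + 149])
            pairs.append((f"p{i}", m1, m2))
            truth[f"p{i}"] = "gA"
        m = s.evaluate_retrieval(s.assign_pairs(pairs, idx), truth, ["gA"])
        row = m.per_genome.loc["gA"]
        assert row.recall == 0.0 and row.precision == 1.0  # 0/0 := 1

    def test_count_arithmetic(self):
        # 90 correct + 10 wrong unique assignments to genome A, 100 truly from A
        truth = {f"a{i}": "A" for i in range(100)}
        truth |= {f"b{i}": "B" for i in range(10)}
        assignments = [
            s.PairAssignment(f"a{i}", "unique", genome_id="A") for i in range(90)
        ]
        assignments += [
            s.PairAssignment(f"a{i}", "unmapped") for i in range(90, 100)
        ]
        assignments += [
            s.PairAssignment(f"b{i}", "unique", genome_id="A") for i in range(10)
        ]
        m = s.evaluate_retrieval(assignments, truth, ["A"])
        row = m.per_genome.loc["A"]
        assert row.precision == pytest.approx(0.9)
        assert row.recall == pytest.approx(0.9)

    def test_unknown_fragment_id_raises(self):
        with pytest.raises(ValueError):
            s.evaluate_retrieval(
                [s.PairAssignment("ghost", "unmapped")], {"real": "A"}
            )


class TestGridSearch:
    def test_grid_of_one_matches_direct_evaluation(self, small_refset):
        w = s.sample_expression(small_refset, seed=31)
        frags = s.simulate_fragments(small_refset, w, 300, seed=32)
        pairs = [(f.fragment_id, f.mate1_seq, f.mate2_seq) for f in frags]
        truth = {f.fragment_id: f.genome_id for f in frags}
        table = s.grid_search(pairs, truth, small_refset, {"max_mismatch": [1]})
        assert len(table) == 1
        direct = s.evaluate_retrieval(
            s.assign_pairs(pairs, s.build_index(small_refset, 21),
                           s.AssignParams(max_mismatch=1)),
            truth,
        )
        assert table.loc[0, "f1"] == pytest.approx(direct.micro_f1)

    def test_widening_max_frag_never_loses_unique_pairs(self, small_refset):
        w = s.sample_expression(small_refset, seed=33)
        frags = s.simulate_fragments(small_refset, w, 400, insert_sd=60, seed=34)
        pairs = [(f.fragment_id, f.mate1_seq, f.mate2_seq) for f in frags]
        truth = {f.fragment_id: f.genome_id for f in frags}
        table = s.grid_search(
            pairs, truth, small_refset, {"max_frag": [150, 200, 300, 450]}
        )
        uniques = table.sort_values("max_frag")["n_unique"].to_list()
        assert uniques == sorted(uniques)

    def test_empty_grid_rejected(self, small_refset):
        with pytest.raises(ValueError):
            s.grid_search([], {}, small_refset, {})


class TestSamRoundTrip:
    def test_sam_import_reproduces_count_table(self, community, tmp_path):
        refset = community["refset"]
        sam = tmp_path / "out.sam"
        subset = community["assignments"][:1000]
        s.write_sam(subset, refset, sam)
        back = s.read_sam(sam, refset)
        direct = s.count_fragments(subset, refset.cds)
        via_sam = s.count_fragments(back, refset.cds)
        assert via_sam.counts == direct.counts
        assert via_sam.tallies == direct.tallies
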