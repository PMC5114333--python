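"""Shrinkage statistics, expansion decisions, leading-node selection and
multi-leaf record assignment."""

import itertools

import numpy as np
import pytest

from medhier.config import RunConfig
from medhier.corpus import QARecord
from medhier.kernels import KernelEngine
from medhier.shrinkage import (
    Bipartition,
    assign_records,
    avg_relation,
    bipartition,
    inter_intra,
    leading_nodes,
    should_expand,
)
from medhier.topics import fit_topic_model

from .oracles import avg_relation_bruteforce, leading_nodes_bruteforce


def make_records(vocab_blocks, per_block, doc_len=20, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for b, vocab in enumerate(vocab_blocks):
        for i in range(per_block):
            rec = QARecord(id=f"b{b}r{i}", question="x")
            rec.tokens = [vocab[j] for j in rng.integers(0, len(vocab), doc_len)]
            rec.question = " ".join(rec.tokens)
            out.append(rec)
    return out


class TestAvgRelation:
    def test_singletons_reduce_to_single_pair(self):
        assert avg_relation(["a"], ["b"], lambda i, j: 0.4) == pytest.approx(0.4)

    def test_constant_similarity_averages_to_constant(self):
        assert avg_relation(["a", "b"], ["c", "d", "e"], lambda i, j: 0.7) == pytest.approx(0.7)

    def test_same_set_includes_identity_pairs(self):
        # literal cross product over A x A includes i = j with S(x, x) = 1
        val = avg_relation(["a", "b"], ["a", "b"], lambda i, j: 0.0)
        assert val == pytest.approx(2 / 4)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        table = {}

        def sim(i, j):
            key = (min(i, j), max(i, j))
            if key not in table:
                table[key] = float(rng.random())
            return table[key]

        a = [f"a{i}" for i in range(3)]
        b = [f"b{i}" for i in range(4)]
        assert avg_relation(a, b, sim) == pytest.approx(avg_relation_bruteforce(a, b, sim))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            avg_relation([], ["a"], lambda i, j: 1.0)


class TestInterIntra:
    def test_statistically_identical_halves_give_inter_two(self):
        # all pairwise similarities equal -> R(A,B) = R(A,V) = R(B,V)
        bip = Bipartition(["a1", "a2"], ["b1", "b2"])
        stats = inter_intra(bip, ["a1", "a2", "b1", "b2"], lambda i, j: 0.6, delta=1.2)
        assert stats.inter == pytest.approx(2.0, rel=0.2)

    def test_perfectly_separated_halves_give_inter_zero(self):
        def sim(i, j):
            return 0.8 if i[0] == j[0] else 0.0

        bip = Bipartition(["a1", "a2"], ["b1", "b2"])
        stats = inter_intra(bip, ["a1", "a2", "b1", "b2"], sim, delta=1.2)
        assert stats.inter == pytest.approx(0.0)

    def test_inter_monotone_in_cross_similarity(self):
        def make_sim(cross):
            return lambda i, j: cross if i[0] != j[0] else 0.8

        bip = Bipartition(["a1", "a2"], ["b1", "b2"])
        members = ["a1", "a2", "b1", "b2"]
        vals = [
            inter_intra(bip, members, make_sim(c), delta=1.2).inter
            for c in (0.6, 0.4, 0.2)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_zero_denominator_flags_degenerate(self):
        # identity pairs keep R(A, V) > 0 for any true bipartition, so the
        # degenerate branch guards custom similarity callables / foreign V
        bip = Bipartition(["a1"], ["b1"])
        stats = inter_intra(bip, ["c1", "c2"], lambda i, j: 0.0, delta=1.2)
        assert stats.degenerate
        assert stats.inter is None

    def test_identity_pairs_keep_denominators_positive(self):
        bip = Bipartition(["a1"], ["b1"])
        stats = inter_intra(bip, ["a1", "b1"], lambda i, j: 0.0, delta=1.2)
        assert not stats.degenerate
        assert stats.r_av == pytest.approx(0.5)  # (S(a1,a1)=1 + 0) / 2
        assert stats.inter == pytest.approx(0.0)


class TestBipartition:
    def test_planted_two_topic_split_recovered(self):
        blocks = [[f"x{i}" for i in range(15)], [f"y{i}" for i in range(15)]]
        records = make_records(blocks, per_block=20, seed=1)
        bip = bipartition(records, seed=0)
        sides = {rid[:2] for rid in bip.node_a}, {rid[:2] for rid in bip.node_b}
        assert sides[0].isdisjoint(sides[1])  # each planted block on one side

    def test_union_covers_parent_and_determinism(self):
        blocks = [[f"x{i}" for i in range(10)], [f"y{i}" for i in range(10)]]
        records = make_records(blocks, per_block=10, seed=2)
        b1 = bipartition(records, seed=5)
        b2 = bipartition(records, seed=5)
        assert set(b1.node_a) | set(b1.node_b) == {r.id for r in records}
        assert (b1.node_a, b1.node_b) == (b2.node_a, b2.node_b)

    def test_too_small_node_rejected(self):
        records = make_records([["x1", "x2"]], per_block=3, seed=3)
        with pytest.raises(ValueError):
            bipartition(records, seed=0)


class TestShouldExpand:
    def test_boundary_inter_equal_delta_still_expands(self):
        # strictly "larger than" terminates, so inter == delta must expand
        records = make_records(
            [[f"x{i}" for i in range(10)], [f"y{i}" for i in range(10)]], 10, seed=4
        )
        sim = lambda i, j: 0.5  # noqa: E731 -> all-equal sims give inter = 2
        expand, stats = should_expand(records, delta=stats_inter(records, sim), sim=sim, seed=0)
        assert expand

    def test_homogeneous_node_terminates(self):
        records = make_records([[f"x{i}" for i in range(20)]], per_block=50, seed=5)
        engine = engine_with_space(records)
        expand, stats = should_expand(records, delta=1.2, sim=engine, seed=0)
        assert not expand
        assert stats.inter is None or stats.inter > 1.2 or stats.degenerate

    def test_two_disjoint_topics_expand(self):
        blocks = [[f"x{i}" for i in range(20)], [f"y{i}" for i in range(20)]]
        records = make_records(blocks, per_block=25, seed=6)
        engine = engine_with_space(records)
        expand, stats = should_expand(records, delta=1.2, sim=engine, seed=0)
        assert expand
        assert stats.inter is not None and stats.inter <= 1.2


def stats_inter(records, sim):
    from medhier.config import stage_seed
    from medhier.shrinkage import bipartition as bp, inter_intra as ii

    bip = bp(records, seed=stage_seed(0, "bipartition"))
    return ii(bip, [r.id for r in records], sim, 0.0).inter


def engine_with_space(records):
    engine = KernelEngine(config=RunConfig(seed=0))
    model = fit_topic_model([r.tokens for r in records], k=2, seed=0)
    engine.set_topic_space(model, records)
    return engine


class TestLeadingNodes:
    def test_worked_gap_example(self):
        # gap after position 2 (0.35 - 0.10 = 0.25) is maximal
        assert leading_nodes(np.array([0.4, 0.35, 0.1, 0.1, 0.05])) == [0, 1]

    def test_single_child(self):
        assert leading_nodes(np.array([1.0])) == [0]

    def test_uniform_posterior_selects_exactly_one(self):
        assert len(leading_nodes(np.full(5, 0.2))) == 1

    def test_matches_bruteforce_on_grid_vectors(self):
        # all probability vectors of length <= 4 on a coarse 0.1 grid
        for m in (2, 3, 4):
            for combo in itertools.product(range(11), repeat=m - 1):
                if sum(combo) > 10:
                    continue
                probs = [c / 10 for c in combo] + [(10 - sum(combo)) / 10]
                p = np.array(probs)
                assert leading_nodes(p) == leading_nodes_bruteforce(p)


@pytest.fixture(scope="module")
def planted_assignment():
    """Three disjoint topics plus records mixing the first two.

    The gap rule needs at least three children to dual-assign: a mixture
    record's sorted posterior (~0.48, 0.48, 0.04) puts the largest gap after
    position 2.
    """
    blocks = [
        [f"x{i}" for i in range(15)],
        [f"y{i}" for i in range(15)],
        [f"z{i}" for i in range(15)],
    ]
    rng = np.random.default_rng(9)
    records = make_records(blocks, per_block=40, seed=7)
    for i in range(20):
        rec = QARecord(id=f"mix{i}", question="x")
        toks = [blocks[0][j] for j in rng.integers(0, 15, 10)]
        toks += [blocks[1][j] for j in rng.integers(0, 15, 10)]
        rec.tokens = toks
        records.append(rec)
    model = fit_topic_model([r.tokens for r in records], k=3, seed=0)
    return records, model


class TestAssignRecords:
    @pytest.fixture()
    def planted(self, planted_assignment):
        return planted_assignment

    def test_children_cover_parent(self, planted):
        records, model = planted
        table = assign_records(model, records)
        assigned = {rid for ids in table.values() for rid in ids}
        assert assigned == {r.id for r in records}

    def test_pure_records_get_single_child(self, planted):
        records, model = planted
        table = assign_records(model, records)
        membership = {}
        for child, ids in table.items():
            for rid in ids:
                membership.setdefault(rid, []).append(child)
        pure = [r.id for r in records if r.id.startswith("b")]
        single = sum(1 for rid in pure if len(membership[rid]) == 1)
        assert single / len(pure) > 0.9

    def test_mixed_records_get_both_children(self, planted):
        records, model = planted
        table = assign_records(model, records)
        membership = {}
        for child, ids in table.items():
            for rid in ids:
                membership.setdefault(rid, []).append(child)
        mixed = [r.id for r in records if r.id.startswith("mix")]
        both = sum(1 for rid in mixed if len(membership[rid]) == 2)
        assert both / len(mixed) >= 0.7
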