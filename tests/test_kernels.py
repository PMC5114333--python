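"""Similarity kernels: term cosine with concept boosting, subset-tree kernel,
Jensen-Shannon topic kernel, and their fusion."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medhier.config import RunConfig
from medhier.corpus import QARecord
from medhier.kernels import (
    LN2,
    KernelEngine,
    SimilarityWeights,
    fuse,
    js_to_similarity,
    stkn,
    stkn_chain,
    syntactic_kernel_raw,
    topic_kernel,
    weighted_term_kernel,
)
from medhier.lexicon import ConceptLexicon, TermEntry
from medhier.nlp import LexiconPosTagger, ParseTree, RightBranchingParser

from .oracles import js_divergence_bruteforce, random_tree, stkn_bruteforce


def rec(rid: str, tokens: list[str]) -> QARecord:
    r = QARecord(id=rid, question=" ".join(tokens))
    r.tokens = list(tokens)
    return r


SYMPTOM_LEXICON = ConceptLexicon(
    [("fever", TermEntry("T1", "fever", "sign or symptom"))]
)


class TestWeightedTermKernel:
    def test_identical_records_give_one(self):
        a = rec("a", ["fever", "cough", "cough"])
        assert weighted_term_kernel(a, a) == pytest.approx(1.0)

    def test_half_overlap_without_boost(self):
        a = rec("a", ["fever", "cough"])
        b = rec("b", ["fever", "headache"])
        # cosine of (1,1,0) and (1,0,1)
        assert weighted_term_kernel(a, b) == pytest.approx(0.5)

    def test_boosted_concept_raises_similarity(self):
        a = rec("a", ["fever", "cough"])
        b = rec("b", ["fever", "headache"])
        val = weighted_term_kernel(
            a, b, SYMPTOM_LEXICON, boost=2.0, boosted_groups=("sign or symptom",)
        )
        # cosine of (2,1,0) and (2,0,1) = 4/5
        assert val == pytest.approx(0.8)

    def test_empty_bag_gives_zero(self):
        a = rec("a", [])
        b = rec("b", ["fever"])
        assert weighted_term_kernel(a, b) == 0.0

    def test_symmetry(self):
        a = rec("a", ["x", "y", "z"])
        b = rec("b", ["y", "z", "w"])
        assert weighted_term_kernel(a, b) == weighted_term_kernel(b, a)


class TestSTKN:
    def test_disjoint_labels_share_nothing(self):
        t1 = ParseTree("A", (ParseTree("x"),))
        t2 = ParseTree("B", (ParseTree("y"),))
        assert stkn(t1, t2) == 0

    def test_empty_tree_rejected(self):
        leaf = ParseTree("x")
        with pytest.raises(ValueError):
            stkn(leaf, leaf)

    def test_matches_bruteforce_enumeration_on_small_trees(self):
        rng = random.Random(42)
        for _ in range(200):
            t1 = random_tree(rng, max_nodes=8)
            t2 = random_tree(rng, max_nodes=8)
            assert stkn(t1, t2) == stkn_bruteforce(t1, t2)
            assert stkn(t1, t2) == stkn(t2, t1)  # symmetry

    def test_chain_fast_path_equals_generic(self):
        rng = random.Random(7)
        vocab = ["fever", "cough", "pain", "neck", "ache", "zz"]
        tagger = LexiconPosTagger({w: rng.choice(["Noun", "Adjective", "Verb"]) for w in vocab})
        parser = RightBranchingParser(tagger)
        for _ in range(100):
            s1 = rng.choices(vocab, k=rng.randint(1, 7))
            s2 = rng.choices(vocab, k=rng.randint(1, 7))
            generic = stkn(parser.parse(" ".join(s1)), parser.parse(" ".join(s2)))
            fast = stkn_chain(s1, tagger.tag(s1), s2, tagger.tag(s2))
            assert fast == generic


class TestSyntacticKernel:
    def test_single_sentence_records_reduce_to_stkn(self):
        parser = RightBranchingParser(LexiconPosTagger({}))
        a = QARecord(id="a", question="fever cough")
        b = QARecord(id="b", question="fever cough")
        t = parser.parse("fever cough")
        assert syntactic_kernel_raw(a, b, parser) == pytest.approx(stkn(t, t))

    def test_sentence_duplication_leaves_value_unchanged(self):
        parser = RightBranchingParser(LexiconPosTagger({}))
        a = QARecord(id="a", question="fever cough")
        b = QARecord(id="b", question="fever pain")
        base = syntactic_kernel_raw(a, b, parser)
        a2 = QARecord(id="a2", question="fever cough", answers=["fever cough"])
        b2 = QARecord(id="b2", question="fever pain", answers=["fever pain"])
        assert syntactic_kernel_raw(a2, b2, parser) == pytest.approx(base)


class TestTopicKernel:
    def test_identity_gives_zero(self):
        p = np.array([0.3, 0.7])
        assert topic_kernel(p, p) == 0.0

    def test_disjoint_supports_reach_ln2(self):
        assert topic_kernel(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_hand_evaluated_mixture_case(self):
        val = topic_kernel(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        assert val == pytest.approx(0.215762, abs=1e-6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            topic_kernel(np.array([1.0]), np.array([0.5, 0.5]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_js_and_bounds(self, data):
        k = data.draw(st.integers(2, 6))
        raw_p = data.draw(st.lists(st.floats(1e-6, 1.0), min_size=k, max_size=k))
        raw_q = data.draw(st.lists(st.floats(1e-6, 1.0), min_size=k, max_size=k))
        p = np.array(raw_p) / sum(raw_p)
        q = np.array(raw_q) / sum(raw_q)
        val = topic_kernel(p, q)
        assert val == pytest.approx(js_divergence_bruteforce(p, q), abs=1e-10)
        assert val == pytest.approx(topic_kernel(q, p), abs=1e-12)
        assert 0.0 <= val <= math.log(2) + 1e-12


class TestFusion:
    def test_degenerate_weights_select_one_kernel(self):
        w = SimilarityWeights(1.0, 0.0, 0.0)
        assert fuse(0.37, 0.9, 0.1, w) == pytest.approx(0.37)

    def test_all_ones_fuse_to_one(self):
        w = SimilarityWeights(0.2, 0.3, 0.5)
        assert fuse(1.0, 1.0, 0.0, w) == pytest.approx(1.0)

    def test_max_divergence_maps_to_zero_similarity(self):
        w = SimilarityWeights(0.0, 0.0, 1.0)
        assert fuse(0.5, 0.5, math.log(2), w) == pytest.approx(0.0)
        assert js_to_similarity(LN2) == 0.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            SimilarityWeights(0.5, 0.6, 0.2)
        with pytest.raises(ValueError):
            SimilarityWeights(-0.1, 0.6, 0.5)

    def test_grid_enumerates_simplex_lattice(self):
        grid = SimilarityWeights.grid(0.05)
        # lattice size: sum_{i=0..20} (21-i) = 231
        assert len(grid) == 231
        assert all(abs(sum(w.as_tuple()) - 1) < 1e-9 for w in grid)
        assert len({w.as_tuple() for w in grid}) == len(grid)


class TestSimilarityMatrix:
    def test_two_identical_records_phi1_only(self):
        cfg = RunConfig(betas=(1.0, 0.0, 0.0))
        engine = KernelEngine(config=cfg)
        a, b = rec("a", ["fever", "cough"]), rec("b", ["fever", "cough"])
        sm = engine.similarity_matrix([a, b])
        assert np.allclose(sm.W, [[0, 1], [1, 0]])
        assert np.allclose(sm.d, [1, 1])

    def test_matrix_matches_pairwise_calls(self):
        rng = random.Random(1)
        vocab = ["a", "b", "c", "d", "e", "f"]
        cfg = RunConfig(betas=(1.0, 0.0, 0.0))
        engine = KernelEngine(config=cfg)
        records = [rec(f"r{i}", rng.choices(vocab, k=5)) for i in range(5)]
        sm = engine.similarity_matrix(records)
        assert np.allclose(sm.W, sm.W.T)
        for i in range(5):
            for j in range(5):
                expect = 0.0 if i == j else engine.phi1(records[i], records[j])
                assert sm.W[i, j] == pytest.approx(expect, abs=1e-12)

    def test_all_zero_matrix_warns(self):
        cfg = RunConfig(betas=(1.0, 0.0, 0.0))
        engine = KernelEngine(config=cfg)
        a, b = rec("a", ["x"]), rec("b", ["y"])
        with pytest.warns(UserWarning, match="all-zero"):
            sm = engine.similarity_matrix([a, b])
        assert sm.isolated.all()
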