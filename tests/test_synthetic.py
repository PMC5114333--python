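"""The synthetic generator: structure, determinism, and the properties the
downstream stages rely on."""

import numpy as np
import pytest

from medhier.synthetic import (
    GeneratorConfig,
    generate_corpus,
    generate_dataset,
    generate_lexicon_and_reference,
    generate_queries,
    generate_synonym_table,
    generate_topic_tree,
)


class TestTopicTree:
    def test_branching_arithmetic(self):
        tree = generate_topic_tree(GeneratorConfig(branching=(3, 3), seed=0))
        internal = [n for n in tree.nodes.values() if n.children and n.parent is not None]
        leaves = tree.leaves()
        assert len(internal) == 3 and len(leaves) == 9

    def test_same_seed_identical_distributions(self):
        t1 = generate_topic_tree(GeneratorConfig(seed=4))
        t2 = generate_topic_tree(GeneratorConfig(seed=4))
        for nid in t1.nodes:
            d1, d2 = t1.nodes[nid].dist, t2.nodes[nid].dist
            if d1 is not None:
                assert np.array_equal(d1, d2)

    def test_zero_shared_fraction_gives_disjoint_sibling_supports(self):
        cfg = GeneratorConfig(branching=(3,), shared_fraction=0.0, seed=1)
        tree = generate_topic_tree(cfg)
        leaves = tree.leaves()
        supports = [set(np.nonzero(l.dist)[0]) for l in leaves]
        for i in range(len(supports)):
            for j in range(i + 1, len(supports)):
                assert supports[i].isdisjoint(supports[j])


class TestCorpus:
    def test_record_count_arithmetic(self):
        cfg = GeneratorConfig(branching=(3, 3), docs_per_leaf=20, seed=2)
        corpus, truth = generate_corpus(generate_topic_tree(cfg), cfg)
        assert len(corpus) == 9 * 20

    def test_mixture_rate_zero_gives_single_memberships(self):
        cfg = GeneratorConfig(branching=(2, 2), docs_per_leaf=15, mixture_rate=0.0, seed=3)
        _, truth = generate_corpus(generate_topic_tree(cfg), cfg)
        assert all(len(m) == 1 for m in truth.memberships.values())

    def test_mixture_rate_one_gives_double_memberships(self):
        cfg = GeneratorConfig(branching=(2, 2), docs_per_leaf=15, mixture_rate=1.0, seed=3)
        _, truth = generate_corpus(generate_topic_tree(cfg), cfg)
        assert all(len(m) == 2 for m in truth.memberships.values())

    def test_records_have_text_fields(self):
        cfg = GeneratorConfig(branching=(2,), docs_per_leaf=10, seed=5)
        corpus, _ = generate_corpus(generate_topic_tree(cfg), cfg)
        for rec in corpus:
            assert rec.question.strip()


class TestLexiconAndReference:
    def test_every_topic_present_in_both(self):
        tree = generate_topic_tree(GeneratorConfig(seed=6))
        lexicon, ref = generate_lexicon_and_reference(tree)
        for nid, node in tree.nodes.items():
            if node.parent is None:
                continue
            assert node.concept_id in ref
            for variant in node.concept_variants:
                entry = lexicon.lookup(variant)
                assert entry is not None and entry.term_id == node.concept_id

    def test_plural_variant_maps_to_same_terminology(self):
        tree = generate_topic_tree(GeneratorConfig(seed=7))
        lexicon, _ = generate_lexicon_and_reference(tree)
        leaf = tree.leaves()[0]
        singular, plural = leaf.concept_variants[0], leaf.concept_variants[1]
        assert plural.endswith("s")
        assert lexicon.lookup(singular).term_id == lexicon.lookup(plural).term_id

    def test_reference_depth_mirrors_tree_depth(self):
        import networkx as nx

        tree = generate_topic_tree(GeneratorConfig(branching=(2, 2, 2), seed=8))
        _, ref = generate_lexicon_and_reference(tree)
        depth = max(
            nx.shortest_path_length(ref.graph, "T_root", n)
            for n in ref.graph if ref.graph.out_degree(n) == 0
        )
        assert depth == tree.depth()


class TestQueries:
    def test_substitution_rate_zero_preserves_question(self):
        cfg = GeneratorConfig(branching=(2,), docs_per_leaf=10, paraphrase_rate=0.0,
                              n_queries=5, seed=9)
        tree = generate_topic_tree(cfg)
        corpus, truth = generate_corpus(tree, cfg)
        queries = generate_queries(corpus, truth, cfg)
        for q in queries:
            assert q.text == corpus.by_id[q.source_id].question

    def test_alias_table_at_rate_one_gives_zero_token_overlap(self):
        cfg = GeneratorConfig(branching=(2,), docs_per_leaf=10, paraphrase_rate=1.0,
                              n_queries=5, synonym_style="alias", seed=10)
        tree = generate_topic_tree(cfg)
        corpus, truth = generate_corpus(tree, cfg)
        queries = generate_queries(corpus, truth, cfg)
        for q in queries:
            src = set(corpus.by_id[q.source_id].question.split())
            assert src.isdisjoint(set(q.text.split()))

    def test_rotate_table_substitutes_in_place_with_same_topic_words(self):
        cfg = GeneratorConfig(branching=(2,), docs_per_leaf=10, paraphrase_rate=1.0,
                              n_queries=5, seed=10)
        tree = generate_topic_tree(cfg)
        corpus, truth = generate_corpus(tree, cfg)
        table = generate_synonym_table(tree)
        queries = generate_queries(corpus, truth, cfg)
        for q in queries:
            src_tokens = corpus.by_id[q.source_id].question.split()
            out_tokens = q.text.split()
            assert len(src_tokens) == len(out_tokens)
            assert all(o == table[s] for s, o in zip(src_tokens, out_tokens))

    def test_synonym_table_has_no_fixed_points(self):
        tree = generate_topic_tree(GeneratorConfig(seed=11))
        table = generate_synonym_table(tree)
        assert all(a != b for a, b in table.items())
        assert set(tree.vocab) <= set(table)  # covers the full vocabulary

    def test_exactly_one_source_gain_per_query(self):
        cfg = GeneratorConfig(branching=(2, 2), docs_per_leaf=10, n_queries=8, seed=12)
        ds = generate_dataset(cfg)
        for q in ds.queries:
            assert sum(1 for g in q.gains.values() if g == 2) == 1
            assert q.gains[q.source_id] == 2


class TestDataset:
    def test_full_determinism_across_calls(self):
        d1 = generate_dataset(GeneratorConfig(branching=(2, 2), docs_per_leaf=10,
                                              n_queries=3, seed=13))
        d2 = generate_dataset(GeneratorConfig(branching=(2, 2), docs_per_leaf=10,
                                              n_queries=3, seed=13))
        assert [r.to_dict() for r in d1.corpus] == [r.to_dict() for r in d2.corpus]
        assert [q.text for q in d1.queries] == [q.text for q in d2.queries]
        assert d1.prior.to_dict() == d2.prior.to_dict()

    def test_prior_examples_are_pure_first_level_records(self):
        ds = generate_dataset(GeneratorConfig(branching=(2, 2), docs_per_leaf=10,
                                              seed_examples_per_category=5, seed=14))
        for cat, recs in ds.prior.examples.items():
            for rec in recs:
                mems = ds.truth.memberships[rec.id]
                assert len(mems) == 1 and mems[0].startswith(cat)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(branching=(1,))
        with pytest.raises(ValueError):
            GeneratorConfig(mixture_rate=1.5)
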