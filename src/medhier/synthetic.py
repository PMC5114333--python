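"""Synthetic fixtures: a known topic tree generating QA records, an aligned
toy lexicon and reference taxonomy, and paraphrased queries.

The generator emulates the statistical structure the organization scheme
assumes so every stage is testable offline:

* a rooted topic tree with the configured branching; each topic owns a
  mostly-private vocabulary block, children refine their parent's support
  (own block + a slice of the parent's + a global shared slice);
* QA records sampled from one leaf topic — or, at the mixture rate, a 50/50
  blend of two sibling leaves, emulating multi-concern questions;
* one planted terminology per topic with several surface phrase variants
  (including a plural) injected into that topic's records, an exact-match
  lexicon mapping the variants to the terminology, and a reference taxonomy
  mirroring the true tree over terminology ids;
* paraphrased queries built by substituting a fraction of a source question's
  tokens with same-topic synonyms from a generated derangement table —
  lexically disjoint at rate 1 yet topically identical, emulating the
  vocabulary gap.

Everything is driven by one seed; identical seeds give identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus, QARecord
from .hierarchy import DomainPrior
from .lexicon import ConceptLexicon, TermEntry
from .nlp import LexiconPosTagger

__all__ = [
    "GeneratorConfig",
    "TopicNode",
    "TopicTree",
    "GroundTruth",
    "SynthQuery",
    "generate_topic_tree",
    "generate_corpus",
    "generate_lexicon_and_reference",
    "generate_queries",
    "generate_dataset",
    "SyntheticDataset",
]

CONNECTOR = "having"  # delimiter word, tagged Verb by the toy tagger

_SEM_GROUPS = (
    "disease or syndrome",
    "sign or symptom",
    "body part, organ, or organ component",
    "neoplasm",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate a community health-QA crawl at desk scale: short
    records (mean 30 tokens), a two-level topic structure, a fifth of the
    records mixing two sibling concerns, and half of a query's tokens
    paraphrased away.
    """

    branching: tuple[int, ...] = (3, 3)
    vocab_per_topic: int = 40
    shared_fraction: float = 0.1
    docs_per_leaf: int = 200
    doc_len_mean: float = 30.0
    doc_len_dispersion: float = 10.0
    mixture_rate: float = 0.2
    paraphrase_rate: float = 0.5
    concept_rate: float = 0.8       # chance a record carries its leaf concept phrase
    parent_concept_rate: float = 0.5  # chance it carries each ancestor's concept
    seed_examples_per_category: int = 50
    n_queries: int = 50
    synonym_style: str = "rotate"  # "rotate": in-vocabulary same-topic words;
                                   # "alias": disjoint out-of-vocabulary aliases
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b < 2 for b in self.branching):
            raise ValueError("branching entries must be >= 2")
        for name in ("shared_fraction", "mixture_rate", "paraphrase_rate",
                     "concept_rate", "parent_concept_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.vocab_per_topic < 4:
            raise ValueError("vocab_per_topic must be >= 4")
        if self.synonym_style not in ("rotate", "alias"):
            raise ValueError("synonym_style must be 'rotate' or 'alias'")


@dataclass
class TopicNode:
    id: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    depth: int = 0
    word_ids: list[int] = field(default_factory=list)   # private block
    dist: np.ndarray | None = None                       # over global vocab
    concept_id: str = ""
    concept_words: list[str] = field(default_factory=list)
    concept_variants: list[str] = field(default_factory=list)


@dataclass
class TopicTree:
    root_id: str
    nodes: dict[str, TopicNode]
    vocab: list[str]
    shared_word_ids: list[int]

    def leaves(self) -> list[TopicNode]:
        return [n for n in self.nodes.values() if not n.children and n.parent is not None]

    def depth(self) -> int:
        return max(n.depth for n in self.nodes.values())

    def ancestors(self, nid: str) -> list[TopicNode]:
        out = []
        node = self.nodes[nid]
        while node.parent is not None:
            node = self.nodes[node.parent]
            if node.parent is not None:  # exclude the root container
                out.append(node)
        return out


@dataclass
class SynthQuery:
    qid: str
    text: str
    source_id: str
    gains: dict[str, int]  # record id -> graded relevance (2 source, 1 same leaf)


@dataclass
class GroundTruth:
    tree: TopicTree
    memberships: dict[str, list[str]]      # record id -> true leaf topic ids
    first_level: dict[str, list[str]]      # level-1 topic id -> record ids
    node_concept: dict[str, str]           # topic id -> terminology id
    queries: list[SynthQuery] = field(default_factory=list)


def generate_topic_tree(config: GeneratorConfig) -> TopicTree:
    """Build the true topic tree with per-topic word distributions."""
    rng = np.random.default_rng(config.seed)
    nodes: dict[str, TopicNode] = {"t": TopicNode(id="t", parent=None, depth=0)}
    level = ["t"]
    for b in config.branching:
        nxt = []
        for pid in level:
            for i in range(b):
                nid = f"{pid}.{i}"
                nodes[nid] = TopicNode(id=nid, parent=pid, depth=nodes[pid].depth + 1)
                nodes[pid].children.append(nid)
                nxt.append(nid)
        level = nxt

    vocab: list[str] = []

    def new_block(n: int) -> list[int]:
        start = len(vocab)
        vocab.extend(f"w{start + i:04d}" for i in range(n))
        return list(range(start, start + n))

    shared = new_block(config.vocab_per_topic)
    order = sorted(nodes)  # deterministic allocation order
    for nid in order:
        node = nodes[nid]
        if node.parent is None:
            continue
        node.word_ids = new_block(config.vocab_per_topic)
        # three dedicated concept words per topic (deranged by a 3-cycle in
        # the synonym table) and surface variants incl. a plural form
        base = len(vocab)
        words = [f"kw{base + i:04d}" for i in range(3)]
        vocab.extend(words)
        node.concept_words = words
        node.concept_id = f"T_{nid}"
        a, b2, c = words
        node.concept_variants = [f"{a} {b2}", f"{a} {b2}s", f"{c} {b2}"]

    V = len(vocab)
    s = config.shared_fraction
    for nid in order:
        node = nodes[nid]
        if node.parent is None:
            continue
        parent = nodes[node.parent]
        dist = np.zeros(V)
        own_mass = 1.0 - s - (s if parent.word_ids else 0.0)
        weights = rng.dirichlet(np.full(len(node.word_ids), 5.0))
        dist[node.word_ids] = own_mass * weights
        if parent.word_ids and s > 0:
            pw = rng.dirichlet(np.full(len(parent.word_ids), 5.0))
            dist[parent.word_ids] = s * pw
        if s > 0:
            sw = rng.dirichlet(np.full(len(shared), 5.0))
            dist[shared] += s * sw
        node.dist = dist / dist.sum()
    return TopicTree(root_id="t", nodes=nodes, vocab=vocab, shared_word_ids=shared)


def _doc_length(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return max(10, int(rng.negative_binomial(dispersion, p)))


def generate_corpus(tree: TopicTree, config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Sample QA records from the leaf topics (with sibling mixtures)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    leaves = sorted(tree.leaves(), key=lambda n: n.id)
    records: list[QARecord] = []
    memberships: dict[str, list[str]] = {}
    first_level: dict[str, list[str]] = {}
    node_concept = {
        n.id: n.concept_id for n in tree.nodes.values() if n.parent is not None
    }

    def level1_of(nid: str) -> str:
        node = tree.nodes[nid]
        while tree.nodes[node.parent].parent is not None:  # type: ignore[index]
            node = tree.nodes[node.parent]  # type: ignore[index]
        return node.id

    rid = 0
    for leaf in leaves:
        siblings = [
            tree.nodes[c] for c in tree.nodes[leaf.parent].children if c != leaf.id
        ] if leaf.parent else []
        for _ in range(config.docs_per_leaf):
            sources = [leaf]
            if siblings and rng.random() < config.mixture_rate:
                sources.append(siblings[rng.integers(len(siblings))])
            length = _doc_length(rng, config.doc_len_mean, config.doc_len_dispersion)
            counts = [length - length // 2, length // 2][: len(sources)]
            if len(sources) == 1:
                counts = [length]
            draws = [
                rng.choice(len(tree.vocab), size=c, p=src.dist)
                for src, c in zip(sources, counts)
            ]
            tokens = [tree.vocab[w] for d in draws for w in d]
            if len(sources) > 1:
                order = rng.permutation(len(tokens))
                tokens = [tokens[i] for i in order]
            # planted concept phrases: the leaf concept goes into the
            # question, ancestor concepts into the answer
            leaf_extra: list[str] = []
            anc_extra: list[str] = []
            for src in sources:
                if rng.random() < config.concept_rate:
                    variant = src.concept_variants[rng.integers(len(src.concept_variants))]
                    # verb-tagged connector delimits the phrase on the left so
                    # it is not absorbed into an adjacent noun run
                    leaf_extra.extend([CONNECTOR] + variant.split())
                for anc in tree.ancestors(src.id):
                    if rng.random() < config.parent_concept_rate:
                        variant = anc.concept_variants[rng.integers(len(anc.concept_variants))]
                        anc_extra.extend([CONNECTOR] + variant.split())
            n_q = max(4, int(0.6 * len(tokens)))
            n_a = max(1, int(0.3 * len(tokens)))
            question = " ".join(tokens[:n_q] + leaf_extra)
            answer = " ".join(tokens[n_q : n_q + n_a] + anc_extra)
            tags = tokens[n_q + n_a :][:4]
            rec_id = f"r{rid:05d}"
            rid += 1
            records.append(
                QARecord(id=rec_id, question=question,
                         answers=[answer] if answer else [], tags=tags)
            )
            memberships[rec_id] = sorted({s.id for s in sources})
            if len(sources) == 1:
                first_level.setdefault(level1_of(leaf.id), []).append(rec_id)
    corpus = Corpus(records)
    truth = GroundTruth(
        tree=tree, memberships=memberships, first_level=first_level,
        node_concept=node_concept,
    )
    return corpus, truth


def generate_lexicon_and_reference(tree: TopicTree):
    """Toy lexicon (phrase variants -> planted terminologies) and a reference
    taxonomy mirroring the true tree over terminology ids."""
    from .evaluation import ReferenceTaxonomy

    lexicon = ConceptLexicon()
    edges: list[tuple[str, str]] = []
    names: dict[str, str] = {}
    root_term = "T_root"
    names[root_term] = "health topics"
    for nid in sorted(tree.nodes):
        node = tree.nodes[nid]
        if node.parent is None:
            continue
        group = _SEM_GROUPS[hash_mod(nid, len(_SEM_GROUPS))]
        entry = TermEntry(node.concept_id, f"concept {nid}", group)
        names[node.concept_id] = entry.term_name
        for variant in node.concept_variants:
            lexicon.add(variant, entry)
        # single concept words boost the weighted term kernel
        for w in node.concept_words:
            lexicon.add(w, entry)
        parent = tree.nodes[node.parent]
        parent_term = root_term if parent.parent is None else parent.concept_id
        edges.append((parent_term, node.concept_id))
    return lexicon, ReferenceTaxonomy(edges, names)


def hash_mod(text: str, n: int) -> int:
    import zlib

    return zlib.crc32(text.encode()) % n


def generate_synonym_table(tree: TopicTree, style: str = "rotate") -> dict[str, str]:
    """Fixed-point-free substitution table.

    ``rotate`` (default): words cycle within their vocabulary block, so a
    substitute is a different word of the same topic that does occur in other
    records of that topic.  ``alias``: every word maps to a dedicated
    out-of-vocabulary alias, so a fully substituted query shares no token
    with any record.
    """
    if style == "alias":
        table = {w: f"x{w}" for w in tree.vocab}
        for w in list(table):
            table[w + "s"] = table[w] + "s"
        table[CONNECTOR] = "experiencing"
        return table
    table: dict[str, str] = {}

    def cycle(words: list[str]) -> None:
        if len(words) < 2:
            return
        for a, b in zip(words, words[1:] + words[:1]):
            table[a] = b

    cycle([tree.vocab[i] for i in tree.shared_word_ids])
    for nid in sorted(tree.nodes):
        node = tree.nodes[nid]
        if node.parent is None:
            continue
        cycle([tree.vocab[i] for i in node.word_ids])
        cycle(list(node.concept_words))
    for w in list(table):
        if w.startswith("kw"):
            table[w + "s"] = table[w] + "s"
    table[CONNECTOR] = "experiencing"
    return table


def generate_queries(
    corpus: Corpus, truth: GroundTruth, config: GeneratorConfig
) -> list[SynthQuery]:
    """Paraphrased queries with graded relevance (2 source, 1 same leaf)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    synonyms = generate_synonym_table(truth.tree, config.synonym_style)
    pure = [rid for rid, m in sorted(truth.memberships.items()) if len(m) == 1]
    if not pure:
        pure = sorted(truth.memberships)
    n = min(config.n_queries, len(pure))
    chosen = rng.choice(len(pure), size=n, replace=False)
    leaf_members: dict[str, set[str]] = {}
    for rid, mems in truth.memberships.items():
        for leaf in mems:
            leaf_members.setdefault(leaf, set()).add(rid)
    queries: list[SynthQuery] = []
    for qi, idx in enumerate(sorted(chosen.tolist())):
        rid = pure[idx]
        rec = corpus.by_id[rid]
        tokens = rec.question.split()
        out = [
            synonyms.get(t, t) if rng.random() < config.paraphrase_rate else t
            for t in tokens
        ]
        gains = {rid: 2}
        for leaf in truth.memberships[rid]:
            for other in leaf_members[leaf]:
                if other != rid:
                    gains[other] = max(gains.get(other, 0), 1)
        queries.append(SynthQuery(qid=f"q{qi:03d}", text=" ".join(out),
                                  source_id=rid, gains=gains))
    return queries


@dataclass
class SyntheticDataset:
    corpus: Corpus
    truth: GroundTruth
    lexicon: ConceptLexicon
    reference: "object"
    prior: DomainPrior
    tagger: LexiconPosTagger
    queries: list[SynthQuery]
    config: GeneratorConfig


def generate_tag_table(tree: TopicTree, seed: int) -> dict[str, str]:
    """POS table for the toy tagger: concept words are nouns; filler words get
    a realistic mix of classes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    tags = ("Noun", "Adjective", "Verb", "Preposition", "Adverb")
    probs = np.array([0.45, 0.2, 0.2, 0.05, 0.1])
    table: dict[str, str] = {CONNECTOR: "Verb"}
    for w in tree.vocab:
        if w.startswith("kw"):
            table[w] = "Noun"
            table[w + "s"] = "Noun"  # plural surface variants
        else:
            table[w] = tags[int(rng.choice(len(tags), p=probs))]
    return table


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """One-call bundle: corpus, ground truth, lexicon, reference taxonomy,
    domain prior (seed examples from pure first-level records), toy tagger,
    and paraphrased queries."""
    cfg = config or GeneratorConfig()
    tree = generate_topic_tree(cfg)
    corpus, truth = generate_corpus(tree, cfg)
    lexicon, reference = generate_lexicon_and_reference(tree)
    queries = generate_queries(corpus, truth, cfg)
    truth.queries = queries

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    categories = sorted(truth.first_level)
    examples: dict[str, list[QARecord]] = {}
    for cat in categories:
        ids = sorted(truth.first_level[cat])
        k = min(cfg.seed_examples_per_category, len(ids))
        take = rng.choice(len(ids), size=k, replace=False)
        examples[cat] = [corpus.by_id[ids[i]] for i in sorted(take.tolist())]
    prior = DomainPrior(categories=categories, examples=examples)
    tagger = LexiconPosTagger(generate_tag_table(tree, cfg.seed), default="Verb")
    return SyntheticDataset(
        corpus=corpus, truth=truth, lexicon=lexicon, reference=reference,
        prior=prior, tagger=tagger, queries=queries, config=cfg,
    )


# -- file emission (CLI `simulate`) ----------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    from .corpus import write_corpus

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": out / "corpus.jsonl",
        "lexicon": out / "lexicon.tsv",
        "reference": out / "reference.tsv",
        "prior": out / "prior.json",
        "queries": out / "queries.jsonl",
        "truth": out / "truth.json",
        "tags": out / "tags.tsv",
    }
    write_corpus(ds.corpus, paths["corpus"])
    ds.lexicon.write_tsv(paths["lexicon"])
    ds.reference.write_tsv(paths["reference"])
    ds.prior.write_json(paths["prior"])
    with open(paths["queries"], "w", encoding="utf-8") as fh:
        for q in ds.queries:
            fh.write(json.dumps(
                {"id": q.qid, "text": q.text, "source": q.source_id, "gains": q.gains},
                sort_keys=True) + "\n")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "memberships": {k: v for k, v in sorted(ds.truth.memberships.items())},
                "node_concept": ds.truth.node_concept,
                "first_level": {k: sorted(v) for k, v in ds.truth.first_level.items()},
            },
            fh, sort_keys=True,
        )
    ds.tagger.write_tsv(paths["tags"])
    return paths
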