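"""Hierarchy construction: prior-knowledge first layer, then BFS expansion.

The first layer under the root comes from domain knowledge: a list of
category names, each with seed example records, from which one binary
margin classifier per category is trained (positives vs an equal-size seeded
random sample of other categories' positives).  Every corpus record joins the
categories whose classifier fires; a record firing none is routed to its
best-scoring category, so the first layer covers the corpus.

Below the first layer the tree grows breadth-first.  At each node: too-small
nodes become leaves; otherwise the shrinkage test decides whether the node is
specific enough to stop; otherwise the child count is selected by held-out
perplexity, an LDA model is fitted, and each record is assigned to its
leading child topics (overlap allowed).  A configurable depth cap bounds the
recursion as a safety net.  Finally every node is labeled with terminologies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import LinearSVC

from .config import RunConfig, stage_seed
from .corpus import Corpus, QARecord, TokenNormalizer, contextualize
from .kernels import KernelEngine, weighted_bag
from .lexicon import ConceptLexicon
from .nlp import PosTagger
from .profiling import NodeLabel, label_node
from .shrinkage import assign_records, should_expand
from .topics import TopicModel, fit_topic_model, select_child_count

__all__ = [
    "DomainPrior",
    "HierarchyNode",
    "Hierarchy",
    "CategoryClassifiers",
    "train_category_classifiers",
    "build_first_layer",
    "build_hierarchy",
]

log = logging.getLogger(__name__)

ROOT_ID = "root"


@dataclass
class DomainPrior:
    """Ordered first-layer category names with seed example records."""

    categories: list[str]
    examples: dict[str, list[QARecord]]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError("domain prior needs at least 2 categories")
        for cat in self.categories:
            if len(self.examples.get(cat, [])) < 2:
                raise ValueError(f"category {cat!r} needs at least 2 seed examples")

    def to_dict(self) -> dict:
        return {
            "categories": [
                {"name": c, "examples": [r.to_dict() for r in self.examples[c]]}
                for c in self.categories
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainPrior":
        cats, ex = [], {}
        for item in d["categories"]:
            cats.append(item["name"])
            ex[item["name"]] = [
                QARecord(
                    id=str(r["id"]), question=str(r["question"]),
                    answers=[str(a) for a in r.get("answers", [])],
                    tags=[str(t) for t in r.get("tags", [])],
                )
                for r in item["examples"]
            ]
        return cls(cats, ex)

    @classmethod
    def read_json(cls, path: str | Path) -> "DomainPrior":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class HierarchyNode:
    id: str
    parent: str | None
    children: list[str] = field(default_factory=list)
    members: list[str] = field(default_factory=list)
    model: TopicModel | None = None
    child_topics: dict[str, int] = field(default_factory=dict)  # child id -> topic index
    labels: list[NodeLabel] = field(default_factory=list)
    depth: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "parent": self.parent,
            "children": list(self.children),
            "members": list(self.members),
            "model": self.model.to_dict() if self.model is not None else None,
            "child_topics": dict(self.child_topics),
            "labels": [[l.term_id, l.term_name, l.score] for l in self.labels],
            "depth": self.depth,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchyNode":
        return cls(
            id=d["id"], parent=d["parent"], children=list(d["children"]),
            members=list(d["members"]),
            model=TopicModel.from_dict(d["model"]) if d.get("model") else None,
            child_topics={k: int(v) for k, v in d.get("child_topics", {}).items()},
            labels=[NodeLabel(t, n, int(s)) for t, n, s in d.get("labels", [])],
            depth=int(d["depth"]), diagnostics=d.get("diagnostics", {}),
        )


class CategoryClassifiers:
    """One binary margin classifier per first-layer category over weighted
    term bags; serializable without pickling."""

    def __init__(
        self,
        categories: list[str],
        vocab: dict[str, int],
        coefs: np.ndarray,
        intercepts: np.ndarray,
        lexicon: ConceptLexicon | None = None,
        boost: float = 2.0,
        boosted_groups: tuple[str, ...] = (),
    ) -> None:
        self.categories = categories
        self.vocab = vocab
        self.coefs = np.asarray(coefs, dtype=float)      # n_cat x V
        self.intercepts = np.asarray(intercepts, dtype=float)
        self.lexicon = lexicon
        self.boost = boost
        self.boosted_groups = boosted_groups

    def _features(self, rec: QARecord) -> np.ndarray:
        x = np.zeros(len(self.vocab))
        bag = weighted_bag(rec, self.lexicon, self.boost, self.boosted_groups)
        for tok, w in bag.items():
            j = self.vocab.get(tok)
            if j is not None:
                x[j] = w
        return x

    def margins(self, rec: QARecord) -> dict[str, float]:
        x = self._features(rec)
        m = self.coefs @ x + self.intercepts
        return dict(zip(self.categories, m.tolist()))

    def to_dict(self) -> dict:
        return {
            "categories": self.categories,
            "vocab": self.vocab,
            "coefs": self.coefs.tolist(),
            "intercepts": self.intercepts.tolist(),
            "boost": self.boost,
            "boosted_groups": list(self.boosted_groups),
        }

    @classmethod
    def from_dict(cls, d: dict, lexicon: ConceptLexicon | None = None) -> "CategoryClassifiers":
        return cls(
            categories=list(d["categories"]),
            vocab={k: int(v) for k, v in d["vocab"].items()},
            coefs=np.array(d["coefs"], dtype=float),
            intercepts=np.array(d["intercepts"], dtype=float),
            lexicon=lexicon,
            boost=float(d.get("boost", 2.0)),
            boosted_groups=tuple(d.get("boosted_groups", ())),
        )


def train_category_classifiers(
    prior: DomainPrior,
    seed: int = 0,
    lexicon: ConceptLexicon | None = None,
    config: RunConfig | None = None,
) -> CategoryClassifiers:
    """Train per-category positives-vs-sampled-negatives linear classifiers.

    Negatives are an equal-size (or configured-size) seeded random sample
    from the other categories' positives.
    """
    cfg = config or RunConfig()
    norm = TokenNormalizer(cfg.stopwords)
    for cat in prior.categories:
        for rec in prior.examples[cat]:
            if not rec.tokens:
                contextualize(rec, norm, cfg.keep_all_answers)

    vocab: dict[str, int] = {}
    bags: dict[str, list[dict[str, float]]] = {}
    for cat in prior.categories:
        bags[cat] = []
        for rec in prior.examples[cat]:
            bag = weighted_bag(rec, lexicon, cfg.concept_boost, cfg.boosted_groups)
            bags[cat].append(bag)
            for tok in bag:
                vocab.setdefault(tok, len(vocab))

    def featurize(bag: dict[str, float]) -> np.ndarray:
        x = np.zeros(len(vocab))
        for tok, w in bag.items():
            x[vocab[tok]] = w
        return x

    coefs, intercepts = [], []
    for ci, cat in enumerate(prior.categories):
        pos = [featurize(b) for b in bags[cat]]
        other = [b for c2 in prior.categories if c2 != cat for b in bags[c2]]
        n_neg = cfg.negative_sample_size or len(pos)
        n_neg = min(n_neg, len(other))
        if n_neg == 0:
            raise ValueError("no negative examples available")
        rng = np.random.default_rng(stage_seed(seed, "neg-sample", cat))
        idx = rng.choice(len(other), size=n_neg, replace=False)
        neg = [featurize(other[i]) for i in sorted(idx)]
        X = np.vstack(pos + neg)
        y = np.array([1] * len(pos) + [0] * len(neg))
        clf = LinearSVC(C=1.0, random_state=stage_seed(seed, "svm", cat), max_iter=5000)
        clf.fit(X, y)
        coefs.append(clf.coef_[0])
        intercepts.append(clf.intercept_[0])
    return CategoryClassifiers(
        list(prior.categories), vocab, np.vstack(coefs), np.array(intercepts),
        lexicon, cfg.concept_boost, cfg.boosted_groups,
    )


def build_first_layer(
    corpus: Corpus,
    classifiers: CategoryClassifiers,
    multilabel: bool = True,
) -> dict[str, list[str]]:
    """Category name -> member record ids.  Multi-membership when several
    classifiers fire; records firing none go to the best-scoring category;
    empty categories are dropped."""
    table: dict[str, list[str]] = {c: [] for c in classifiers.categories}
    for rec in corpus:
        margins = classifiers.margins(rec)
        fired = [c for c, m in margins.items() if m > 0.0]
        if not multilabel or not fired:
            # argmax fallback; ties break to the earlier category
            best = max(
                classifiers.categories,
                key=lambda c: (margins[c], -classifiers.categories.index(c)),
            )
            fired = [best]
        for c in fired:
            table[c].append(rec.id)
    return {c: ids for c, ids in table.items() if ids}


@dataclass
class Hierarchy:
    """Rooted profiled tree over the corpus; root members = whole corpus."""

    nodes: dict[str, HierarchyNode]
    root_id: str = ROOT_ID
    config: RunConfig = field(default_factory=RunConfig)
    classifiers: CategoryClassifiers | None = None
    topic_space: TopicModel | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.root_id not in self.nodes:
            raise ValueError("missing root node")
        seen: set[str] = set()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise ValueError(f"cycle or duplicate reachability at node {nid}")
            seen.add(nid)
            node = self.nodes[nid]
            member_set = set(node.members)
            for cid in node.children:
                child = self.nodes.get(cid)
                if child is None:
                    raise ValueError(f"dangling child id {cid}")
                if child.parent != nid:
                    raise ValueError(f"parent link mismatch at {cid}")
                if not set(child.members) <= member_set:
                    raise ValueError(f"child {cid} members exceed parent {nid}")
                stack.append(cid)
        if seen != set(self.nodes):
            raise ValueError("disconnected nodes present")

    @property
    def root(self) -> HierarchyNode:
        return self.nodes[self.root_id]

    def leaves(self) -> list[HierarchyNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def depth(self) -> int:
        return max(n.depth for n in self.nodes.values())

    def adjacent_pairs(self) -> list[tuple[HierarchyNode, HierarchyNode]]:
        return [
            (node, self.nodes[cid])
            for node in self.nodes.values()
            for cid in node.children
        ]

    # -- store -------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "root": self.root_id,
            "nodes": {nid: n.to_dict() for nid, n in sorted(self.nodes.items())},
            "config": self.config.to_dict(),
            "classifiers": self.classifiers.to_dict() if self.classifiers else None,
            "topic_space": self.topic_space.to_dict() if self.topic_space else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict, lexicon: ConceptLexicon | None = None) -> "Hierarchy":
        return cls(
            nodes={nid: HierarchyNode.from_dict(nd) for nid, nd in d["nodes"].items()},
            root_id=d["root"],
            config=RunConfig.from_dict(d["config"]),
            classifiers=(
                CategoryClassifiers.from_dict(d["classifiers"], lexicon)
                if d.get("classifiers")
                else None
            ),
            topic_space=(
                TopicModel.from_dict(d["topic_space"]) if d.get("topic_space") else None
            ),
        )

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def read_json(cls, path: str | Path, lexicon: ConceptLexicon | None = None) -> "Hierarchy":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh), lexicon)


def build_hierarchy(
    corpus: Corpus,
    prior: DomainPrior,
    config: RunConfig | None = None,
    lexicon: ConceptLexicon | None = None,
    tagger: PosTagger | None = None,
    engine: KernelEngine | None = None,
    seed: int | None = None,
) -> Hierarchy:
    """Construct the full profiled hierarchy breadth-first.

    Returns a :class:`Hierarchy` whose root holds the entire corpus, whose
    first layer comes from the domain-prior classifiers, and whose deeper
    nodes come from alternating shrinkage tests and perplexity-tuned
    expansion.  Nodes are profiled with terminology labels when a lexicon and
    tagger are supplied.
    """
    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    norm = TokenNormalizer(cfg.stopwords)
    for rec in corpus:
        if not rec.tokens:
            contextualize(rec, norm, cfg.keep_all_answers)

    engine = engine or KernelEngine(lexicon=lexicon, config=cfg)
    if engine.topic_space is None and cfg.betas[2] > 0:
        # corpus-level topic space for the latent topic kernel
        docs = [r.tokens for r in corpus]
        report = select_child_count(
            docs, (cfg.k_min, min(cfg.k_max, len(docs) - 1)),
            holdout_fraction=cfg.holdout_fraction,
            seed=stage_seed(seed, "topic-space"),
            alpha=cfg.alpha, eta=cfg.eta, max_iter=cfg.lda_max_iter,
        )
        space = fit_topic_model(
            docs, report.selected_k, alpha=cfg.alpha, eta=cfg.eta,
            seed=stage_seed(seed, "topic-space-fit"), max_iter=cfg.lda_max_iter,
        )
        engine.set_topic_space(space, list(corpus))

    classifiers = train_category_classifiers(
        prior, seed=stage_seed(seed, "classifiers"), lexicon=lexicon, config=cfg
    )
    first = build_first_layer(corpus, classifiers, cfg.first_layer_multilabel)

    nodes: dict[str, HierarchyNode] = {}
    root = HierarchyNode(id=ROOT_ID, parent=None, members=corpus.ids, depth=0)
    nodes[ROOT_ID] = root

    queue: list[str] = []
    for ci, cat in enumerate(classifiers.categories):
        if cat not in first:
            continue
        nid = f"{ROOT_ID}.{ci}"
        nodes[nid] = HierarchyNode(
            id=nid, parent=ROOT_ID, members=first[cat], depth=1,
            diagnostics={"category": cat},
        )
        root.children.append(nid)
        queue.append(nid)

    while queue:
        nid = queue.pop(0)
        node = nodes[nid]
        members = [corpus.by_id[i] for i in node.members]
        if len(members) < cfg.min_node_size:
            node.diagnostics["leaf_reason"] = "below-min-size"
            continue
        if node.depth >= cfg.depth_cap:
            node.diagnostics["leaf_reason"] = "depth-cap"
            continue
        expand, stats = should_expand(
            members, cfg.delta, engine,
            seed=stage_seed(seed, "shrink", nid),
            sample_cap=cfg.shrinkage_sample,
        )
        node.diagnostics["inter"] = stats.inter
        node.diagnostics["intra"] = stats.intra
        if not expand:
            node.diagnostics["leaf_reason"] = "shrinkage" if not stats.degenerate else "degenerate"
            continue
        docs = [m.tokens for m in members]
        k_hi = min(cfg.k_max, len(docs) - 1)
        report = select_child_count(
            docs, (cfg.k_min, k_hi), holdout_fraction=cfg.holdout_fraction,
            seed=stage_seed(seed, "select-k", nid),
            alpha=cfg.alpha, eta=cfg.eta, max_iter=cfg.lda_max_iter,
        )
        node.diagnostics["selected_k"] = report.selected_k
        node.diagnostics["perplexity_table"] = [[k, p] for k, p in report.table]
        model = fit_topic_model(
            docs, report.selected_k, alpha=cfg.alpha, eta=cfg.eta,
            seed=stage_seed(seed, "fit", nid), max_iter=cfg.lda_max_iter,
        )
        assignment = assign_records(model, members)
        if len(assignment) < 2:
            node.diagnostics["leaf_reason"] = "single-child-collapse"
            continue
        node.model = model
        for topic_idx, child_members in assignment.items():
            cid = f"{nid}.{topic_idx}"
            nodes[cid] = HierarchyNode(
                id=cid, parent=nid, members=child_members, depth=node.depth + 1,
            )
            node.children.append(cid)
            node.child_topics[cid] = topic_idx
            queue.append(cid)

    hierarchy = Hierarchy(
        nodes=nodes, config=cfg, classifiers=classifiers,
        topic_space=engine.topic_space,
    )

    if lexicon is not None and tagger is not None:
        for node in hierarchy.nodes.values():
            if node.id == ROOT_ID:
                continue
            texts: list[str] = []
            for rid in node.members:
                texts.extend(corpus.by_id[rid].sentences())
            node.labels = label_node(
                texts, lexicon, tagger, k=cfg.phrase_candidates, top_n=cfg.labels_per_node
            )
    return hierarchy
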