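"""Model/Results façade over the pipeline.

:class:`TopicHierarchyModel` is constructed from data (a corpus and a domain
prior, optionally a concept lexicon and POS tagger); :meth:`fit` builds the
profiled hierarchy and returns a :class:`HierarchyResults` carrying the tree,
per-node diagnostics (shrinkage statistics, selected child counts,
perplexity tables), a text ``summary()``, and the downstream operations —
``search`` and ``evaluate`` — bound to the fitted state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .config import RunConfig
from .corpus import Corpus
from .evaluation import EvalReport, ReferenceTaxonomy, evaluate_hierarchy, ndcg_at_n
from .hierarchy import DomainPrior, Hierarchy, build_hierarchy
from .kernels import KernelEngine
from .lexicon import ConceptLexicon
from .nlp import PosTagger
from .retrieval import flat_search, search

__all__ = ["TopicHierarchyModel", "HierarchyResults"]


class TopicHierarchyModel:
    """Unfitted organization model: data plus configuration."""

    def __init__(
        self,
        corpus: Corpus,
        prior: DomainPrior,
        lexicon: ConceptLexicon | None = None,
        tagger: PosTagger | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.corpus = corpus
        self.prior = prior
        self.lexicon = lexicon
        self.tagger = tagger
        self.config = config or RunConfig()

    @classmethod
    def from_files(
        cls,
        corpus_path: str | Path,
        prior_path: str | Path,
        lexicon_path: str | Path | None = None,
        tags_path: str | Path | None = None,
        config: RunConfig | None = None,
    ) -> "TopicHierarchyModel":
        from .corpus import read_corpus
        from .nlp import LexiconPosTagger

        corpus = read_corpus(corpus_path)
        prior = DomainPrior.read_json(prior_path)
        lexicon = ConceptLexicon.read_tsv(lexicon_path) if lexicon_path else None
        tagger = LexiconPosTagger.read_tsv(tags_path, default="Verb") if tags_path else None
        return cls(corpus, prior, lexicon, tagger, config)

    def fit(self, seed: int | None = None) -> "HierarchyResults":
        cfg = self.config if seed is None else self.config.replace(seed=seed)
        engine = KernelEngine(lexicon=self.lexicon, config=cfg)
        hierarchy = build_hierarchy(
            self.corpus, self.prior, config=cfg, lexicon=self.lexicon,
            tagger=self.tagger, engine=engine, seed=cfg.seed,
        )
        return HierarchyResults(self, hierarchy, engine)


class HierarchyResults:
    """Fitted hierarchy plus the machinery to query and evaluate it."""

    def __init__(
        self, model: TopicHierarchyModel, hierarchy: Hierarchy, engine: KernelEngine
    ) -> None:
        self.model = model
        self.hierarchy = hierarchy
        self.engine = engine

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        h = self.hierarchy
        lines = [
            "Topic hierarchy fit",
            "===================",
            f"records:        {len(self.model.corpus)}",
            f"nodes:          {len(h.nodes)} ({len(h.leaves())} leaves)",
            f"depth:          {h.depth()}",
            f"first layer:    {len(h.root.children)} categories",
            f"topic space k:  {h.topic_space.k if h.topic_space else '-'}",
            "",
            f"{'node':<16}{'depth':>6}{'size':>7}{'k':>4}{'inter':>8}  top label",
        ]
        for nid in sorted(h.nodes):
            node = h.nodes[nid]
            if nid == h.root_id:
                continue
            inter = node.diagnostics.get("inter")
            inter_s = f"{inter:.3f}" if isinstance(inter, float) else "-"
            k = node.diagnostics.get("selected_k", "-")
            label = node.labels[0].term_name if node.labels else "-"
            lines.append(
                f"{nid:<16}{node.depth:>6}{len(node.members):>7}{k!s:>4}{inter_s:>8}  {label}"
            )
        return "\n".join(lines)

    def labels_per_record(self) -> float:
        """Average number of leaves each record belongs to."""
        counts: dict[str, int] = {}
        for leaf in self.hierarchy.leaves():
            for rid in leaf.members:
                counts[rid] = counts.get(rid, 0) + 1
        return sum(counts.values()) / max(1, len(counts))

    # -- downstream --------------------------------------------------------
    def search(self, query_text: str, n: int = 10) -> list[tuple[str, float]]:
        return search(
            self.hierarchy, self.model.corpus, query_text, n=n,
            engine=self.engine, config=self.hierarchy.config,
        )

    def search_flat(self, query_text: str, n: int = 10) -> list[tuple[str, float]]:
        return flat_search(self.model.corpus, query_text, n=n, config=self.hierarchy.config)

    def evaluate(
        self,
        ref: ReferenceTaxonomy,
        node_relevant: dict[str, set[str]] | None = None,
        ks: Sequence[int] = (1, 3, 5),
    ) -> EvalReport:
        cfg = self.hierarchy.config
        return evaluate_hierarchy(
            self.hierarchy, ref, node_relevant, ks,
            tuple_labels=cfg.tuple_labels,
            cohesiveness_labels=cfg.cohesiveness_labels,
        )

    def ndcg_for_queries(
        self, queries, n: int = 10, flat: bool = False
    ) -> float:
        """Mean NDCG@n over synthetic queries with graded gains."""
        vals = []
        for q in queries:
            ranked = (
                self.search_flat(q.text, n=n) if flat else self.search(q.text, n=n)
            )
            gains = [q.gains.get(rid, 0) for rid, _ in ranked]
            vals.append(ndcg_at_n(gains, n))
        return sum(vals) / max(1, len(vals))

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        self.hierarchy.write_json(path)

    @classmethod
    def load(
        cls, path: str | Path, model: TopicHierarchyModel
    ) -> "HierarchyResults":
        hierarchy = Hierarchy.read_json(path, model.lexicon)
        engine = KernelEngine(lexicon=model.lexicon, config=hierarchy.config)
        if hierarchy.topic_space is not None:
            engine.set_topic_space(hierarchy.topic_space)
        return cls(model, hierarchy, engine)
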