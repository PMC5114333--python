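"""Evaluation metrics: tuple accuracy and cohesiveness against a reference
taxonomy, S@K / P@K for node labels, NDCG@n for retrieval.

The reference taxonomy (MeSH stand-in) is a rooted tree of terminology ids.
*Tuple accuracy* is the fraction of (parent label, child label) tuples over
adjacent hierarchy nodes that are direct parent-child edges in the
reference.  *Cohesiveness* generalizes this: each labeled pair contributes
1/2^p when the parent's terminology is a proper ancestor of the child's at
directed path length p, and 0 otherwise (including reversed direction), and
the contributions are averaged over all M x N label pairs pooled across
adjacent node pairs — so it lies in [0, 1/2], reaching 1/2 only when every
pair is a direct parent-child relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .hierarchy import Hierarchy

__all__ = [
    "ReferenceTaxonomy",
    "EvalReport",
    "tuple_accuracy",
    "relation_weight",
    "cohesiveness",
    "s_at_k",
    "p_at_k",
    "ndcg_at_n",
]


class ReferenceTaxonomy:
    """Rooted terminology tree with ancestor-path-length queries."""

    def __init__(self, edges: Sequence[tuple[str, str]], names: dict[str, str] | None = None):
        self.graph = nx.DiGraph()
        self.graph.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("reference taxonomy must be acyclic")
        self.names = names or {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    def is_parent(self, parent: str, child: str) -> bool:
        return self.graph.has_edge(parent, child)

    def path_length(self, ancestor: str, descendant: str) -> int | None:
        """Directed path length from ancestor to descendant; None if there is
        no such path (including the reversed direction)."""
        if ancestor not in self.graph or descendant not in self.graph:
            return None
        if ancestor == descendant:
            return None
        try:
            return nx.shortest_path_length(self.graph, ancestor, descendant)
        except nx.NetworkXNoPath:
            return None

    # -- TSV I/O: parent id <TAB> child id ---------------------------------
    @classmethod
    def read_tsv(cls, path: str | Path, names_path: str | Path | None = None) -> "ReferenceTaxonomy":
        edges = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parent, child = line.split("\t")[:2]
                edges.append((parent, child))
        names = {}
        if names_path is not None:
            with open(names_path, "r", encoding="utf-8") as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line.strip():
                        continue
                    tid, name = line.split("\t")[:2]
                    names[tid] = name
        return cls(edges, names)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for parent, child in sorted(self.graph.edges):
                fh.write(f"{parent}\t{child}\n")


def relation_weight(t_parent: str, t_child: str, ref: ReferenceTaxonomy) -> float:
    """1/2^p for a proper ancestor->descendant pair at path length p; else 0."""
    p = ref.path_length(t_parent, t_child)
    if p is None or p < 1:
        return 0.0
    return 1.0 / (2.0**p)


def _node_terms(node, limit: int) -> list[str]:
    terms = [l.term_id for l in node.labels]
    return terms[:limit] if limit > 0 else terms


def tuple_accuracy(
    hierarchy: Hierarchy, ref: ReferenceTaxonomy, labels_per_node: int = 1
) -> tuple[int, int, float | None, int]:
    """(total tuples, correct tuples, accuracy or None, skipped pairs).

    Tuples are all (parent label, child label) pairs over adjacent labeled
    nodes, using each node's top ``labels_per_node`` labels; a tuple is
    correct iff it is a direct parent-child edge in the reference.  Adjacent
    pairs with an unlabeled endpoint are skipped and counted.
    """
    total = correct = skipped = 0
    for parent, child in hierarchy.adjacent_pairs():
        if parent.id == hierarchy.root_id:
            continue  # the root is a container, not a labeled topic
        pterms = _node_terms(parent, labels_per_node)
        cterms = _node_terms(child, labels_per_node)
        if not pterms or not cterms:
            skipped += 1
            continue
        for tp in pterms:
            for tc in cterms:
                total += 1
                if ref.is_parent(tp, tc):
                    correct += 1
    accuracy = (correct / total) if total else None
    return total, correct, accuracy, skipped


def cohesiveness(
    hierarchy: Hierarchy, ref: ReferenceTaxonomy, labels_per_node: int = 0
) -> float | None:
    """Pooled average of relation_weight over all (parent term, child term)
    pairs of adjacent labeled nodes; None when no labeled pair exists."""
    total_weight = 0.0
    pairs = 0
    for parent, child in hierarchy.adjacent_pairs():
        if parent.id == hierarchy.root_id:
            continue
        pterms = _node_terms(parent, labels_per_node)
        cterms = _node_terms(child, labels_per_node)
        for tp in pterms:
            for tc in cterms:
                pairs += 1
                total_weight += relation_weight(tp, tc, ref)
    if pairs == 0:
        return None
    return total_weight / pairs


def s_at_k(ranked: Sequence[str], relevant: set[str], k: int) -> int:
    """1 if any of the top-k ranked labels is relevant, else 0."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return int(any(t in relevant for t in ranked[:k]))


def p_at_k(ranked: Sequence[str], relevant: set[str], k: int) -> float:
    """|C ∩ R| / |C| with C the set of top-k ranked labels."""
    if k < 1:
        raise ValueError("K must be >= 1")
    top = list(ranked[:k])
    if not top:
        return 0.0
    return len(set(top) & relevant) / len(top)


def ndcg_at_n(gains: Sequence[int], n: int) -> float:
    """NDCG with gain 2^rel - 1 and log2(rank+1) discount.

    ``gains`` are the graded relevances (0/1/2) of the returned list in rank
    order; the ideal DCG re-sorts them descending.  Defined as 0 when the
    ideal DCG is 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if any(g not in (0, 1, 2) for g in gains):
        raise ValueError("gains must be graded 0, 1 or 2")

    def dcg(seq: Sequence[int]) -> float:
        return sum((2.0**g - 1.0) / math.log2(r + 2) for r, g in enumerate(seq[:n]))

    ideal = dcg(sorted(gains, reverse=True))
    if ideal == 0.0:
        return 0.0
    return dcg(list(gains)) / ideal


@dataclass
class EvalReport:
    """Aggregated evaluation over one hierarchy (and optionally queries)."""

    total_tuples: int = 0
    correct_tuples: int = 0
    tuple_accuracy: float | None = None
    skipped_pairs: int = 0
    cohesiveness: float | None = None
    s_at_k: dict[int, float] = field(default_factory=dict)
    p_at_k: dict[int, float] = field(default_factory=dict)
    ndcg: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_tuples": self.total_tuples,
            "correct_tuples": self.correct_tuples,
            "tuple_accuracy": self.tuple_accuracy,
            "skipped_pairs": self.skipped_pairs,
            "cohesiveness": self.cohesiveness,
            "s_at_k": {str(k): v for k, v in self.s_at_k.items()},
            "p_at_k": {str(k): v for k, v in self.p_at_k.items()},
            "ndcg": {str(k): v for k, v in self.ndcg.items()},
        }


def evaluate_hierarchy(
    hierarchy: Hierarchy,
    ref: ReferenceTaxonomy,
    node_relevant: dict[str, set[str]] | None = None,
    ks: Sequence[int] = (1, 3, 5),
    tuple_labels: int = 1,
    cohesiveness_labels: int = 0,
) -> EvalReport:
    """Full hierarchy report: tuple accuracy, cohesiveness, and (given
    per-node relevant terminology sets) average S@K / P@K over labeled nodes."""
    total, correct, acc, skipped = tuple_accuracy(hierarchy, ref, tuple_labels)
    report = EvalReport(
        total_tuples=total, correct_tuples=correct, tuple_accuracy=acc,
        skipped_pairs=skipped,
        cohesiveness=cohesiveness(hierarchy, ref, cohesiveness_labels),
    )
    if node_relevant:
        for k in ks:
            s_vals, p_vals = [], []
            for nid, relevant in node_relevant.items():
                node = hierarchy.nodes.get(nid)
                if node is None or not node.labels:
                    continue
                ranked = [l.term_id for l in node.labels]
                s_vals.append(s_at_k(ranked, relevant, k))
                p_vals.append(p_at_k(ranked, relevant, k))
            if s_vals:
                report.s_at_k[k] = sum(s_vals) / len(s_vals)
                report.p_at_k[k] = sum(p_vals) / len(p_vals)
    return report
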