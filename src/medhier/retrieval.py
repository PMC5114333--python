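"""Hierarchy-routed retrieval with graph random-walk reranking.

A query is treated as a QA record (question part only), routed from the root
down to matching leaves — first layer by the category classifiers, deeper
levels by inferring the query's topic mixture at each node and descending
into its leading children — and the member records of the reached leaves form
the candidate pool.  Candidates get initial relevance scores from the fused
kernel and are reranked by iterating

    y = 1/(1+lambda) * W D^{-1} y + lambda/(1+lambda) * y_bar

to its fixed point, where W is the candidates' pairwise similarity matrix and
D its diagonal row-sum matrix.  The iteration is a contraction for
lambda > 0; isolated candidates (zero row sum) bypass the walk and keep their
initial scores.  Large lambda pins y to y_bar, small lambda smooths relevance
over the similarity graph — which is what bridges the vocabulary gap between
paraphrased queries and archived records.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .corpus import Corpus, QARecord, TokenNormalizer
from .hierarchy import Hierarchy, HierarchyNode, ROOT_ID
from .kernels import KernelEngine
from .shrinkage import leading_nodes
from .topics import infer_mixture

__all__ = [
    "Query",
    "RankState",
    "make_query_record",
    "route_query",
    "initial_scores",
    "random_walk_rank",
    "random_walk_solve",
    "search",
    "flat_search",
]

log = logging.getLogger(__name__)


@dataclass
class Query:
    """Free-text query: the question part only, contextualized."""

    text: str
    tokens: list[str] = field(default_factory=list)


def make_query_record(text: str, config: RunConfig | None = None) -> QARecord:
    cfg = config or RunConfig()
    # id is content-derived so engine caches never alias distinct queries
    qid = f"__query__{zlib.crc32(text.encode('utf-8')):08x}"
    rec = QARecord(id=qid, question=text)
    norm = TokenNormalizer(cfg.stopwords)
    rec.tokens = norm(text)
    return rec


def route_query(
    hierarchy: Hierarchy, query: QARecord, engine: KernelEngine | None = None
) -> list[HierarchyNode]:
    """Route a query down to leaf nodes.

    First layer: categories whose classifier fires (best-scoring category if
    none).  Below: infer the query's topic mixture under each node's model
    and descend into the leading children.  Degenerate queries (no
    in-vocabulary tokens anywhere) reach all first-layer nodes.
    """
    root = hierarchy.root
    if hierarchy.classifiers is None:
        starts = [hierarchy.nodes[c] for c in root.children]
    else:
        margins = hierarchy.classifiers.margins(query)
        cats = [c for c, m in margins.items() if m > 0.0]
        if not cats:
            if not query.tokens:
                log.warning("query has no usable tokens: routing to all first-layer nodes")
                cats = list(margins)
            else:
                cats = [max(margins, key=lambda c: margins[c])]
        cat_to_node = {
            hierarchy.nodes[c].diagnostics.get("category"): hierarchy.nodes[c]
            for c in root.children
        }
        starts = [cat_to_node[c] for c in cats if c in cat_to_node]
        if not starts:
            starts = [hierarchy.nodes[c] for c in root.children]

    leaves: list[HierarchyNode] = []
    stack = list(starts)
    seen: set[str] = set()
    while stack:
        node = stack.pop()
        if node.id in seen:
            continue
        seen.add(node.id)
        if node.is_leaf:
            leaves.append(node)
            continue
        if node.model is None:
            stack.extend(hierarchy.nodes[c] for c in node.children)
            continue
        post = infer_mixture(node.model, query)
        lead = set(leading_nodes(post))
        picked = [
            hierarchy.nodes[cid]
            for cid, topic in node.child_topics.items()
            if topic in lead
        ]
        if not picked:  # all leading topics collapsed to empty children
            picked = [hierarchy.nodes[c] for c in node.children]
        stack.extend(picked)
    return sorted(leaves, key=lambda n: n.id)


def initial_scores(
    query: QARecord, candidates: list[QARecord], engine: KernelEngine
) -> np.ndarray:
    """Initial relevance y_bar: fused similarity of the query to each
    candidate, clipped to >= 0."""
    if not candidates:
        raise ValueError("no candidates to score")
    return engine.query_scores(query, candidates)


def random_walk_rank(
    W: np.ndarray,
    y_bar: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 500,
    bypass_isolated: bool = True,
) -> "RankState":
    """Fixed-point iteration of the reranking recurrence from y = y_bar.

    Candidates with zero row sum keep their initial scores when
    ``bypass_isolated`` (their transition column is undefined); with the
    bypass disabled their rows use D^{-1} = 0, giving the closed-form
    fixed point y = lambda/(1+lambda) * y_bar when W = 0.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    W = np.asarray(W, dtype=float)
    y_bar = np.asarray(y_bar, dtype=float)
    n = W.shape[0]
    d = W.sum(axis=1)
    isolated = d == 0.0
    d_inv = np.where(isolated, 0.0, 1.0 / np.where(isolated, 1.0, d))
    A = (W * d_inv[None, :]) / (1.0 + lam)  # W D^{-1} scaled
    b = (lam / (1.0 + lam)) * y_bar
    y = y_bar.copy()
    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        y_new = A @ y + b
        residual = float(np.max(np.abs(y_new - y)))
        y = y_new
        if residual < tol:
            break
    else:
        warnings.warn(f"random walk did not converge in {max_iter} iterations "
                      f"(residual {residual:.2e})")
    if bypass_isolated:
        y = np.where(isolated, y_bar, y)
    return RankState(y=y, y_bar=y_bar, lam=lam, iterations=it, residual=residual,
                     isolated=isolated)


def random_walk_solve(W: np.ndarray, y_bar: np.ndarray, lam: float) -> np.ndarray:
    """Direct solution of the reranking linear system (oracle for the
    iterate): (I - 1/(1+lambda) W D^{-1}) y = lambda/(1+lambda) y_bar."""
    W = np.asarray(W, dtype=float)
    y_bar = np.asarray(y_bar, dtype=float)
    n = W.shape[0]
    d = W.sum(axis=1)
    d_inv = np.where(d == 0.0, 0.0, 1.0 / np.where(d == 0.0, 1.0, d))
    A = np.eye(n) - (W * d_inv[None, :]) / (1.0 + lam)
    return np.linalg.solve(A, (lam / (1.0 + lam)) * y_bar)


@dataclass
class RankState:
    y: np.ndarray
    y_bar: np.ndarray
    lam: float
    iterations: int
    residual: float
    isolated: np.ndarray


def search(
    hierarchy: Hierarchy,
    corpus: Corpus,
    query_text: str,
    n: int = 10,
    engine: KernelEngine | None = None,
    config: RunConfig | None = None,
) -> list[tuple[str, float]]:
    """Hierarchy-routed search: route, pool leaf members, score, rerank.

    Returns the top n (record id, relevance) pairs, relevance descending,
    ties broken by record id.
    """
    cfg = config or hierarchy.config
    engine = engine or KernelEngine(config=cfg)
    if engine.topic_space is None and hierarchy.topic_space is not None:
        engine.set_topic_space(hierarchy.topic_space)
    query = make_query_record(query_text, cfg)
    leaves = route_query(hierarchy, query, engine)
    pool_ids = sorted({rid for leaf in leaves for rid in leaf.members})
    if not pool_ids:
        log.warning("empty candidate pool for query %r", query_text[:50])
        return []
    candidates = [corpus.by_id[rid] for rid in pool_ids]
    y_bar = initial_scores(query, candidates, engine)
    if len(candidates) > cfg.rerank_pool:
        # cap the O(n^2) reranking graph at the strongest initial matches
        keep = np.argsort(-y_bar, kind="stable")[: cfg.rerank_pool]
        keep = np.sort(keep)
        candidates = [candidates[i] for i in keep]
        y_bar = y_bar[keep]
    if len(candidates) == 1:
        ranked = [(candidates[0].id, float(y_bar[0]))]
        return ranked[:n]
    sm = engine.similarity_matrix(candidates)
    state = random_walk_rank(sm.W, y_bar, cfg.lam, cfg.walk_tol, cfg.walk_max_iter)
    order = sorted(
        range(len(candidates)), key=lambda i: (-state.y[i], candidates[i].id)
    )
    return [(candidates[i].id, float(state.y[i])) for i in order[:n]]


def flat_search(
    corpus: Corpus, query_text: str, n: int = 10, config: RunConfig | None = None
) -> list[tuple[str, float]]:
    """Flat term-matching baseline: cosine over raw term bags, whole corpus."""
    cfg = config or RunConfig()
    query = make_query_record(query_text, cfg)
    qbag: dict[str, float] = {}
    for t in query.tokens:
        qbag[t] = qbag.get(t, 0.0) + 1.0
    qn = float(np.sqrt(sum(w * w for w in qbag.values()))) or 1.0
    scored: list[tuple[str, float]] = []
    for rec in corpus:
        bag: dict[str, float] = {}
        for t in rec.tokens:
            bag[t] = bag.get(t, 0.0) + 1.0
        dot = sum(w * bag.get(t, 0.0) for t, w in qbag.items())
        norm = float(np.sqrt(sum(w * w for w in bag.values()))) or 1.0
        scored.append((rec.id, dot / (qn * norm)))
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return scored[:n]
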