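"""Shrinkage test and record assignment.

*Shrinkage* decides whether a node is already specific enough to stop
expanding: the node V is trially bipartitioned into A and B (a 2-topic model
with argmax assignment), average cross-set similarities

    R(A, B) = (1/|A||B|) * sum_{i in A, j in B} S(x_i, x_j)

are computed with the fused kernel as S, and the normalized inter-node
relation

    inter(A, B) = R(A,B)/R(A,V) + R(A,B)/R(B,V)

is compared with the threshold delta: if inter > delta the halves are too
entangled to be split and the node becomes a leaf.

*Assignment* places each record of an expanded node into its leading child
topics: sort the posterior mixture descending, find the largest gap between
adjacent values, and keep every child before that gap — so a record that
mixes two topics lands in both (the loose partition), while a single-topic
record lands in exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .config import RunConfig, stage_seed
from .corpus import QARecord
from .topics import TopicModel, fit_topic_model, infer_mixture

__all__ = [
    "Bipartition",
    "RelationStats",
    "bipartition",
    "avg_relation",
    "inter_intra",
    "should_expand",
    "leading_nodes",
    "assign_records",
]

PairSim = Callable[[str, str], float]


@dataclass
class Bipartition:
    """Trial split of a node's members into two halves A, B with A ∪ B = V."""

    node_a: list[str]
    node_b: list[str]

    def __post_init__(self) -> None:
        if not self.node_a or not self.node_b:
            raise ValueError("both halves of a bipartition must be nonempty")


@dataclass
class RelationStats:
    r_ab: float
    r_av: float
    r_bv: float
    r_aa: float
    r_bb: float
    inter: float | None
    intra: float | None
    delta: float
    degenerate: bool = False


def bipartition(
    members: Sequence[QARecord], seed: int = 0, min_size: int = 4, max_iter: int = 25
) -> Bipartition:
    """Split node members by a 2-topic model (argmax topic per record); if a
    side comes out empty, fall back to a balanced split by first-topic
    probability rank."""
    if len(members) < min_size:
        raise ValueError(f"node below minimum size {min_size} for bipartition")
    docs = [m.tokens for m in members]
    model = fit_topic_model(docs, k=2, seed=seed, max_iter=max_iter)
    p0 = model.doc_topic[:, 0]
    side_a = [m.id for m, p in zip(members, p0) if p >= 0.5]
    side_b = [m.id for m, p in zip(members, p0) if p < 0.5]
    if not side_a or not side_b:
        order = np.argsort(-p0, kind="stable")
        half = len(members) // 2
        side_a = [members[i].id for i in order[:half]]
        side_b = [members[i].id for i in order[half:]]
    return Bipartition(side_a, side_b)


def avg_relation(set_a: Sequence[str], set_b: Sequence[str], sim: PairSim) -> float:
    """Average pairwise similarity over the A x B cross product.

    When A and B are the same set the literal formula includes i = j pairs,
    for which S(x, x) = 1 by convention.
    """
    if not set_a or not set_b:
        raise ValueError("average relation of an empty set is undefined")
    total = 0.0
    for i in set_a:
        for j in set_b:
            total += 1.0 if i == j else sim(i, j)
    return total / (len(set_a) * len(set_b))


def inter_intra(
    bip: Bipartition, parent_members: Sequence[str], sim: PairSim, delta: float
) -> RelationStats:
    """Normalized inter- and intra-node relations of a trial bipartition."""
    a, b, v = bip.node_a, bip.node_b, list(parent_members)
    r_ab = avg_relation(a, b, sim)
    r_av = avg_relation(a, v, sim)
    r_bv = avg_relation(b, v, sim)
    r_aa = avg_relation(a, a, sim)
    r_bb = avg_relation(b, b, sim)
    if r_av <= 0.0 or r_bv <= 0.0:
        return RelationStats(r_ab, r_av, r_bv, r_aa, r_bb, None, None, delta, degenerate=True)
    inter = r_ab / r_av + r_ab / r_bv
    intra = r_aa / r_av + r_bb / r_bv
    return RelationStats(r_ab, r_av, r_bv, r_aa, r_bb, inter, intra, delta)


def should_expand(
    members: Sequence[QARecord],
    delta: float,
    sim: "PairSim | object",
    seed: int = 0,
    sample_cap: int | None = None,
    min_size: int = 4,
) -> tuple[bool, RelationStats]:
    """Expand unless the trial bipartition's inter-node relation exceeds
    delta (strictly greater terminates) or the node is degenerate.

    ``sim`` is either a pair-similarity callable over record ids or a
    :class:`~medhier.kernels.KernelEngine`, in which case the fused
    similarity matrix (tree kernel scaled over this node's pool) is used.
    ``sample_cap`` bounds the members entering the O(n^2) averages; the
    subsample is seeded so the decision is reproducible.
    """
    pool = list(members)
    if sample_cap is not None and len(pool) > sample_cap:
        rng = np.random.default_rng(stage_seed(seed, "shrink-sample"))
        idx = rng.choice(len(pool), size=sample_cap, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    if hasattr(sim, "similarity_matrix"):
        sm = sim.similarity_matrix(pool)
        index = {rid: i for i, rid in enumerate(sm.ids)}
        W = sm.W

        def sim_fn(i: str, j: str) -> float:  # noqa: ANN001
            return float(W[index[i], index[j]])

    else:
        sim_fn = sim  # type: ignore[assignment]
    bip = bipartition(pool, seed=stage_seed(seed, "bipartition"), min_size=min_size)
    stats = inter_intra(bip, [m.id for m in pool], sim_fn, delta)
    if stats.degenerate:
        return False, stats
    assert stats.inter is not None
    return stats.inter <= delta, stats


def leading_nodes(posterior: np.ndarray) -> list[int]:
    """Indices of the leading child topics of a posterior mixture.

    Sort probabilities descending, compute adjacent differences, cut after
    the position of the maximum difference (earliest such position on ties),
    return the child indices before the cut.  A length-1 posterior returns
    that child; an all-equal posterior returns the top-1.
    """
    p = np.asarray(posterior, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("posterior must be a nonempty vector")
    if p.size == 1:
        return [0]
    order = np.argsort(-p, kind="stable")
    sorted_p = p[order]
    gaps = sorted_p[:-1] - sorted_p[1:]
    cut = int(np.argmax(gaps)) + 1  # first maximal gap
    return sorted(int(i) for i in order[:cut])


def assign_records(
    model: TopicModel, members: Sequence[QARecord]
) -> dict[int, list[str]]:
    """Assign each member record to its leading child topics.

    Returns child-topic index -> member record ids; children with no members
    are dropped.  Every record appears in at least one child, so the children
    cover the parent.
    """
    table: dict[int, list[str]] = {}
    for i, rec in enumerate(members):
        if model.doc_topic.shape[0] == len(members):
            post = model.doc_topic[i]
        else:
            post = infer_mixture(model, rec)
        for child in leading_nodes(post):
            table.setdefault(child, []).append(rec.id)
    return {c: ids for c, ids in sorted(table.items()) if ids}
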