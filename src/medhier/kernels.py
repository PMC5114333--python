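"""Pairwise similarity of QA records: three kernels and their linear fusion.

Three complementary views of a record pair are combined:

* **weighted term kernel** — cosine over term counts, with terms whose
  lexicon entry falls in a boosted semantic group (diseases, anatomy,
  symptoms, neoplasms by default) up-weighted by a constant factor;
* **syntactic tree kernel** — the subset-tree kernel STKN (number of parse
  fragments shared by two sentences), summed over all sentence pairs of the
  two records and divided by the product of sentence counts so long records
  are not favored;
* **latent topic kernel** — Jensen–Shannon divergence between the records'
  topic mixtures in a shared topic space.

The fused similarity is a convex combination Φ = β1·Φ1 + β2·Φ2 + β3·Φ3 with
the JS divergence first converted to a similarity (1 − JS/ln 2) so all three
components increase with similarity, and the tree-kernel column min–max
scaled into [0, 1] over the record set at hand so the β weights act on
comparable scales.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from scipy.special import rel_entr

from .config import RunConfig
from .corpus import QARecord
from .lexicon import ConceptLexicon
from .nlp import ParseTree, RightBranchingParser, SentenceParser

__all__ = [
    "SimilarityWeights",
    "SimilarityMatrix",
    "weighted_bag",
    "weighted_term_kernel",
    "stkn",
    "syntactic_kernel_raw",
    "topic_kernel",
    "js_to_similarity",
    "fuse",
    "KernelEngine",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimilarityWeights:
    """Fusion weights (β1, β2, β3); must lie on the probability simplex."""

    beta1: float
    beta2: float
    beta3: float

    def __post_init__(self) -> None:
        b = (self.beta1, self.beta2, self.beta3)
        if any(x < 0 for x in b):
            raise ValueError("fusion weights must be nonnegative")
        if abs(sum(b) - 1.0) > 1e-9:
            raise ValueError("fusion weights must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.beta1, self.beta2, self.beta3)

    @staticmethod
    def grid(step: float = 0.05) -> list["SimilarityWeights"]:
        """The simplex lattice enumerated by grid search over β1, β2 with the
        given step in [0, 1] and β3 = 1 − β1 − β2."""
        n = round(1.0 / step)
        out = []
        for i in range(n + 1):
            for j in range(n + 1 - i):
                b1, b2 = i * step, j * step
                out.append(SimilarityWeights(b1, b2, round(1.0 - b1 - b2, 10)))
        return out


# --------------------------------------------------------------------------
# Φ1: weighted term kernel
# --------------------------------------------------------------------------

def weighted_bag(
    record: QARecord,
    lexicon: ConceptLexicon | None,
    boost: float = 2.0,
    boosted_groups: Sequence[str] = (),
) -> dict[str, float]:
    """Term -> weight map: counts, multiplied once by ``boost`` for terms
    whose lexicon entry is in a boosted semantic group."""
    groups = {g.lower() for g in boosted_groups}
    bag: dict[str, float] = {}
    for tok in record.tokens:
        bag[tok] = bag.get(tok, 0.0) + 1.0
    if lexicon is not None and groups and boost != 1.0:
        for tok in list(bag):
            grp = lexicon.lookup_word_group(tok)
            if grp is not None and grp in groups:
                bag[tok] *= boost
    return bag


def _bag_cosine(a: dict[str, float], b: dict[str, float]) -> float:
    if not a or not b:
        return 0.0
    dot = sum(w * b[t] for t, w in a.items() if t in b)
    na = math.sqrt(sum(w * w for w in a.values()))
    nb = math.sqrt(sum(w * w for w in b.values()))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return min(1.0, dot / (na * nb))


def weighted_term_kernel(
    a: QARecord,
    b: QARecord,
    lexicon: ConceptLexicon | None = None,
    boost: float = 2.0,
    boosted_groups: Sequence[str] = (),
) -> float:
    """Cosine of the two weighted bags; 0 when either bag is empty."""
    if boost < 1:
        raise ValueError("boost must be >= 1")
    ba = weighted_bag(a, lexicon, boost, boosted_groups)
    bb = weighted_bag(b, lexicon, boost, boosted_groups)
    return _bag_cosine(ba, bb)


# --------------------------------------------------------------------------
# Φ2: syntactic tree kernel
# --------------------------------------------------------------------------

def stkn(t1: ParseTree, t2: ParseTree) -> int:
    """Subset-tree kernel: the number of tree fragments common to both parse
    trees, counted by the standard recursion with no decay factor.

    C(n1, n2) is 0 when the productions at n1 and n2 differ, 1 for matching
    preterminals, and otherwise the product over aligned children of
    (1 + C(c1, c2)).  STKN sums C over all internal node pairs.
    """
    if t1.is_leaf or t2.is_leaf:
        raise ValueError("STKN requires nonempty (internal-node-bearing) trees")
    nodes1 = t1.internal_nodes()
    nodes2 = t2.internal_nodes()
    memo: dict[tuple[int, int], int] = {}

    def C(a: ParseTree, b: ParseTree) -> int:
        key = (id(a), id(b))
        hit = memo.get(key)
        if hit is not None:
            return hit
        if a.production() != b.production():
            memo[key] = 0
            return 0
        if a.is_preterminal:
            memo[key] = 1
            return 1
        val = 1
        for ca, cb in zip(a.children, b.children):
            if ca.is_leaf:
                continue
            val *= 1 + C(ca, cb)
        memo[key] = val
        return val

    return sum(C(a, b) for a in nodes1 for b in nodes2)


def stkn_chain(
    words1: Sequence[str], tags1: Sequence[str],
    words2: Sequence[str], tags2: Sequence[str],
) -> float:
    """STKN specialized to right-branching trees over tagged token sequences.

    Equal to :func:`stkn` on the corresponding :class:`RightBranchingParser`
    trees (property-tested), but evaluated by a vectorized backward
    recurrence instead of the generic recursion: for chain nodes,
    C(s_i, s_j) = [tag match]·(1 + [token match])·(1 + C(s_{i+1}, s_{j+1})).
    """
    L1, L2 = len(words1), len(words2)
    if L1 == 0 or L2 == 0:
        raise ValueError("STKN requires nonempty sentences")
    w1 = np.asarray(words1, dtype=object)
    w2 = np.asarray(words2, dtype=object)
    t1 = np.asarray(tags1, dtype=object)
    t2 = np.asarray(tags2, dtype=object)
    T = (t1[:, None] == t2[None, :])
    E = T & (w1[:, None] == w2[None, :])
    Tf = T.astype(float)
    Ef = E.astype(float)
    A = Tf * (1.0 + Ef)
    C = np.zeros((L1, L2))
    C[L1 - 1, L2 - 1] = Tf[L1 - 1, L2 - 1] * (1.0 + Ef[L1 - 1, L2 - 1])
    for i in range(L1 - 2, -1, -1):
        if L2 > 1:
            C[i, : L2 - 1] = A[i, : L2 - 1] * (1.0 + C[i + 1, 1:])
    return float(C.sum() + Ef.sum())


def syntactic_kernel_raw(
    a: QARecord,
    b: QARecord,
    parser: SentenceParser | None = None,
) -> float:
    """Unscaled Φ2: Σ_i Σ_j STKN(T(s_i), T(s_j)) / (|d1|·|d2|), where |d| is
    the sentence count of a record.  Min–max scaling into [0, 1] over the
    current record set is applied downstream (see :class:`KernelEngine`)."""
    parser = parser or RightBranchingParser()
    sa = [s for s in a.sentences() if s.strip()]
    sb = [s for s in b.sentences() if s.strip()]
    if not sa or not sb:
        raise ValueError("record with zero sentences")
    total = 0.0
    trees_b = [parser.parse(s) for s in sb]
    for s1 in sa:
        t1 = parser.parse(s1)
        for t2 in trees_b:
            total += stkn(t1, t2)
    return total / (len(sa) * len(sb))


# --------------------------------------------------------------------------
# Φ3: latent topic kernel (Jensen–Shannon divergence)
# --------------------------------------------------------------------------

def _check_distribution(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError(f"{name} must be a vector")
    if np.any(p < -1e-12):
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1")
    return np.clip(p, 0.0, None)


def topic_kernel(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence 0.5·KL(p‖m) + 0.5·KL(q‖m), m = (p+q)/2,
    natural log.  0 iff p = q; bounded above by ln 2."""
    p = _check_distribution(p, "p")
    q = _check_distribution(q, "q")
    if p.shape != q.shape:
        raise ValueError("topic distributions must share a dimension")
    m = 0.5 * (p + q)
    js = 0.5 * float(rel_entr(p, m).sum()) + 0.5 * float(rel_entr(q, m).sum())
    return min(max(js, 0.0), LN2)


def js_to_similarity(js: float) -> float:
    """Map a JS divergence in [0, ln 2] to a similarity in [0, 1]."""
    return min(1.0, max(0.0, 1.0 - js / LN2))


# --------------------------------------------------------------------------
# Fusion
# --------------------------------------------------------------------------

def fuse(
    phi1: float,
    phi2: float,
    phi3_div: float,
    betas: SimilarityWeights,
    phi3_polarity: str = "similarity",
) -> float:
    """Linear fusion Φ = β1Φ1 + β2Φ2 + β3Φ3.

    ``phi3_div`` is the raw JS divergence; under the default polarity it is
    converted to 1 − JS/ln 2 before fusing so that Φ increases with
    similarity on all three components.
    """
    for name, v in (("phi1", phi1), ("phi2", phi2), ("phi3_div", phi3_div)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if phi3_polarity == "similarity":
        phi3 = js_to_similarity(phi3_div)
    elif phi3_polarity == "divergence":
        phi3 = phi3_div
    else:
        raise ValueError("phi3_polarity must be 'similarity' or 'divergence'")
    return betas.beta1 * phi1 + betas.beta2 * phi2 + betas.beta3 * phi3


# --------------------------------------------------------------------------
# Similarity matrix / engine
# --------------------------------------------------------------------------

@dataclass
class SimilarityMatrix:
    """Symmetric pairwise fused-similarity matrix with row sums.

    ``W[i, i] = 0`` (no self-loops for the random walk); records whose row
    sum is zero are flagged isolated.
    """

    ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.ids)
        if self.W.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")

    @property
    def d(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.d)

    @property
    def isolated(self) -> np.ndarray:
        return self.d == 0.0

    def pair(self, i: str, j: str) -> float:
        return float(self.W[self.ids.index(i), self.ids.index(j)])


class KernelEngine:
    """Corpus-level kernel computations over a shared topic space.

    Caches weighted bags, parse trees, sentence-pair STKN values and topic
    mixtures per record id, so repeated similarity queries (shrinkage tests,
    reranking) do not recompute them.  The topic mixtures come from a single
    corpus-level topic model (set via :meth:`set_topic_space`); until one is
    set, Φ3 contributes its neutral value through a zero divergence between
    identical uniform mixtures.
    """

    def __init__(
        self,
        lexicon: ConceptLexicon | None = None,
        parser: SentenceParser | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.config = config or RunConfig()
        self.lexicon = lexicon
        self.parser = parser or RightBranchingParser()
        self.betas = SimilarityWeights(*self.config.betas)
        self._bags: dict[str, dict[str, float]] = {}
        self._trees: dict[str, list[ParseTree]] = {}
        self._sent_trees: dict[str, ParseTree] = {}
        self._stkn_cache: dict[tuple[str, str], float] = {}
        self._tagged_cache: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
        self._mixtures: dict[str, np.ndarray] = {}
        self.topic_space = None  # TopicModel, set after corpus-level fit

    # -- per-record representations ---------------------------------------
    def bag(self, rec: QARecord) -> dict[str, float]:
        if rec.id not in self._bags:
            self._bags[rec.id] = weighted_bag(
                rec, self.lexicon, self.config.concept_boost, self.config.boosted_groups
            )
        return self._bags[rec.id]

    def trees(self, rec: QARecord) -> list[ParseTree]:
        if rec.id not in self._trees:
            trees = []
            for s in rec.sentences():
                if not s.strip():
                    continue
                if s not in self._sent_trees:
                    self._sent_trees[s] = self.parser.parse(s)
                trees.append(self._sent_trees[s])
            if not trees:
                raise ValueError(f"record {rec.id!r} has zero sentences")
            self._trees[rec.id] = trees
        return self._trees[rec.id]

    def set_topic_space(self, model, records: Sequence[QARecord] = ()) -> None:
        from .topics import infer_mixture  # local import to avoid a cycle

        self.topic_space = model
        self._mixtures.clear()
        for rec in records:
            self._mixtures[rec.id] = infer_mixture(model, rec)

    def mixture(self, rec: QARecord) -> np.ndarray | None:
        if self.topic_space is None:
            return None
        if rec.id not in self._mixtures:
            from .topics import infer_mixture

            self._mixtures[rec.id] = infer_mixture(self.topic_space, rec)
        return self._mixtures[rec.id]

    # -- pairwise kernels --------------------------------------------------
    def phi1(self, a: QARecord, b: QARecord) -> float:
        return _bag_cosine(self.bag(a), self.bag(b))

    def _tagged(self, sentence: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
        hit = self._tagged_cache.get(sentence)
        if hit is None:
            from .nlp import tokenize_words

            words = tuple(tokenize_words(sentence))
            tags = tuple(self.parser.tagger.tag(list(words)))
            hit = (words, tags)
            self._tagged_cache[sentence] = hit
        return hit

    def phi2_raw(self, a: QARecord, b: QARecord) -> float:
        sa = [s for s in a.sentences() if s.strip()]
        sb = [s for s in b.sentences() if s.strip()]
        if not sa or not sb:
            raise ValueError("record with zero sentences")
        fast = isinstance(self.parser, RightBranchingParser)
        total = 0.0
        for s1 in sa:
            for s2 in sb:
                key = (s1, s2) if s1 <= s2 else (s2, s1)
                val = self._stkn_cache.get(key)
                if val is None:
                    if fast:
                        w1, t1 = self._tagged(s1)
                        w2, t2 = self._tagged(s2)
                        if not w1 or not w2:
                            val = 0.0
                        else:
                            val = stkn_chain(w1, t1, w2, t2)
                    else:
                        val = float(stkn(self._parse(s1), self._parse(s2)))
                    self._stkn_cache[key] = val
                total += val
        return total / (len(sa) * len(sb))

    def _parse(self, sentence: str) -> ParseTree:
        if sentence not in self._sent_trees:
            self._sent_trees[sentence] = self.parser.parse(sentence)
        return self._sent_trees[sentence]

    def phi3_div(self, a: QARecord, b: QARecord) -> float:
        pa, pb = self.mixture(a), self.mixture(b)
        if pa is None or pb is None:
            return 0.0
        m = 0.5 * (pa + pb)
        js = 0.5 * float(rel_entr(pa, m).sum()) + 0.5 * float(rel_entr(pb, m).sum())
        return min(max(js, 0.0), LN2)

    # -- matrices ----------------------------------------------------------
    def similarity_matrix(self, records: Sequence[QARecord]) -> SimilarityMatrix:
        """Fused W over a record set; Φ2 is min–max scaled over the set's
        off-diagonal raw values before fusion.  W_ii = 0."""
        n = len(records)
        if n < 2:
            raise ValueError("similarity matrix needs at least 2 records")
        ids = [r.id for r in records]
        b1, b2, b3 = self.betas.as_tuple()

        P1 = self._phi1_matrix(records) if b1 > 0 else np.zeros((n, n))
        P2 = self._phi2_matrix(records) if b2 > 0 else np.zeros((n, n))
        S3 = self._phi3_sim_matrix(records) if b3 > 0 else np.zeros((n, n))

        W = b1 * P1 + b2 * P2 + b3 * S3
        np.fill_diagonal(W, 0.0)
        W = np.clip(0.5 * (W + W.T), 0.0, None)
        sm = SimilarityMatrix(ids, W)
        if np.all(W == 0.0):
            warnings.warn("all-zero similarity matrix: ranking degenerates to initial scores")
        return sm

    def _phi1_matrix(self, records: Sequence[QARecord]) -> np.ndarray:
        vocab: dict[str, int] = {}
        rows, cols, vals = [], [], []
        for i, rec in enumerate(records):
            for tok, w in self.bag(rec).items():
                j = vocab.setdefault(tok, len(vocab))
                rows.append(i)
                cols.append(j)
                vals.append(w)
        if not vocab:
            return np.zeros((len(records), len(records)))
        X = sparse.csr_matrix((vals, (rows, cols)), shape=(len(records), len(vocab)))
        norms = np.sqrt(X.multiply(X).sum(axis=1)).A1
        norms[norms == 0.0] = 1.0
        Xn = sparse.diags(1.0 / norms) @ X
        return np.clip((Xn @ Xn.T).toarray(), 0.0, 1.0)

    def _phi2_matrix(self, records: Sequence[QARecord]) -> np.ndarray:
        n = len(records)
        raw = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                raw[i, j] = raw[j, i] = self.phi2_raw(records[i], records[j])
        off = raw[~np.eye(n, dtype=bool)]
        lo, hi = float(off.min()), float(off.max())
        if hi <= lo:
            return np.zeros((n, n))
        return (raw - lo) / (hi - lo)

    def _phi3_sim_matrix(self, records: Sequence[QARecord]) -> np.ndarray:
        n = len(records)
        if self.topic_space is None:
            return np.ones((n, n))
        M = np.vstack([self.mixture(r) for r in records])  # n x k
        P = M[:, None, :]
        Q = M[None, :, :]
        Mid = 0.5 * (P + Q)
        js = 0.5 * rel_entr(P, Mid).sum(-1) + 0.5 * rel_entr(Q, Mid).sum(-1)
        js = np.clip(js, 0.0, LN2)
        if self.config.phi3_polarity == "divergence":
            return js
        return 1.0 - js / LN2

    # -- query-vs-candidates -----------------------------------------------
    def query_scores(
        self, query: QARecord, candidates: Sequence[QARecord], kernel: str | None = None
    ) -> np.ndarray:
        """Fused similarity of one query record against each candidate; Φ2 is
        min–max scaled over the candidate set."""
        kernel = kernel or self.config.initial_score_kernel
        n = len(candidates)
        p1 = np.array([self.phi1(query, c) for c in candidates])
        if kernel == "phi1":
            return np.clip(p1, 0.0, None)
        b1, b2, b3 = self.betas.as_tuple()
        if b2 > 0:
            raw2 = np.array([self.phi2_raw(query, c) for c in candidates])
            lo, hi = float(raw2.min()), float(raw2.max())
            p2 = (raw2 - lo) / (hi - lo) if hi > lo else np.zeros(n)
        else:
            p2 = np.zeros(n)
        if b3 > 0:
            divs = np.array([self.phi3_div(query, c) for c in candidates])
            if self.config.phi3_polarity == "divergence":
                s3 = divs
            else:
                s3 = 1.0 - divs / LN2
        else:
            s3 = np.zeros(n)
        return np.clip(b1 * p1 + b2 * p2 + b3 * s3, 0.0, None)

    def pair_similarity(self, a: QARecord, b: QARecord, phi2: float | None = None) -> float:
        """Fused similarity for one pair; Φ2 defaults to 0 (no set to scale
        over) unless a pre-scaled value is supplied."""
        return fuse(
            self.phi1(a, b),
            0.0 if phi2 is None else phi2,
            self.phi3_div(a, b),
            self.betas,
            self.config.phi3_polarity,
        )
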