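"""Per-node topic models: LDA fitting, held-out perplexity, child-count selection.

Each hierarchy node's children are the topics of an LDA model fitted on the
node's member records.  The number of children k is selected automatically as
the argmin of held-out perplexity

    perplexity = exp( - sum_i log p(d_i) / sum_i l_i ),

where the sums run over m held-out records and l_i is the (in-vocabulary)
token count of record d_i.  Lower perplexity means the model predicts unseen
records better; ties break toward the smaller k.

Fitting uses batch variational inference (deterministic given the seed);
mixture inference for new documents uses a fixed-point fold-in that depends
only on the stored topic-word matrix, so models survive JSON round-trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from .config import stage_seed
from .corpus import QARecord

__all__ = [
    "TopicModel",
    "PerplexityReport",
    "fit_topic_model",
    "perplexity",
    "select_child_count",
    "infer_mixture",
]

TOKEN_FLOOR = 1e-12  # floor probability per token, guards zero-likelihood docs
_FOLD_IN_ITERS = 40


@dataclass
class TopicModel:
    """Topic-word and document-topic distributions for one node's children."""

    k: int
    vocab: list[str]
    topic_word: np.ndarray  # k x V, rows sum to 1
    doc_topic: np.ndarray   # n x k, rows sum to 1
    alpha: float
    eta: float
    seed: int
    word_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.topic_word = np.asarray(self.topic_word, dtype=float)
        self.doc_topic = np.asarray(self.doc_topic, dtype=float)
        if not self.word_index:
            self.word_index = {w: i for i, w in enumerate(self.vocab)}
        if self.k < 2:
            raise ValueError("a topic model needs k >= 2 children")
        if self.topic_word.shape != (self.k, len(self.vocab)):
            raise ValueError("topic_word shape mismatch")
        if np.abs(self.topic_word.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("topic_word rows must sum to 1")

    def counts_vector(self, tokens: list[str]) -> np.ndarray:
        v = np.zeros(len(self.vocab))
        for t in tokens:
            j = self.word_index.get(t)
            if j is not None:
                v[j] += 1.0
        return v

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "vocab": list(self.vocab),
            "topic_word": self.topic_word.tolist(),
            "doc_topic": self.doc_topic.tolist(),
            "alpha": self.alpha,
            "eta": self.eta,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TopicModel":
        return cls(
            k=int(d["k"]),
            vocab=list(d["vocab"]),
            topic_word=np.array(d["topic_word"], dtype=float),
            doc_topic=np.array(d["doc_topic"], dtype=float),
            alpha=float(d["alpha"]),
            eta=float(d["eta"]),
            seed=int(d["seed"]),
        )


@dataclass
class PerplexityReport:
    """Per-k perplexity table; ``selected_k`` attains the minimum (ties to
    the smaller k)."""

    table: list[tuple[int, float]]
    selected_k: int

    def __post_init__(self) -> None:
        if not self.table:
            raise ValueError("empty perplexity table")
        best = min(p for _, p in self.table)
        winners = [k for k, p in self.table if p == best]
        if self.selected_k != min(winners):
            raise ValueError("selected_k must be the smallest argmin of the table")


def _build_counts(docs: list[list[str]]) -> tuple[sparse.csr_matrix, list[str]]:
    vocab: dict[str, int] = {}
    rows, cols, vals = [], [], []
    for i, doc in enumerate(docs):
        counts: dict[int, float] = {}
        for tok in doc:
            j = vocab.setdefault(tok, len(vocab))
            counts[j] = counts.get(j, 0.0) + 1.0
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    if not vocab:
        raise ValueError("empty vocabulary: no tokens in any document")
    X = sparse.csr_matrix((vals, (rows, cols)), shape=(len(docs), len(vocab)))
    words = [w for w, _ in sorted(vocab.items(), key=lambda kv: kv[1])]
    return X, words


def _fold_in(
    topic_word: np.ndarray, X: sparse.csr_matrix | np.ndarray, alpha: float,
    iters: int = _FOLD_IN_ITERS,
) -> np.ndarray:
    """Fixed-point posterior mixtures for docs in X given fixed topics.

    gamma_dk = alpha + theta_dk * sum_w n_dw * phi_kw / (theta phi)_dw, then
    theta = gamma normalized; uniform init.  Deterministic.
    """
    X = sparse.csr_matrix(X)
    n, V = X.shape
    k = topic_word.shape[0]
    phi = np.clip(topic_word, TOKEN_FLOOR, None)
    theta = np.full((n, k), 1.0 / k)
    for _ in range(iters):
        P = theta @ phi  # n x V predictive per token
        np.clip(P, TOKEN_FLOOR, None, out=P)
        ratio = X.multiply(1.0 / P)  # sparse: n_dw / P_dw on support
        gamma = alpha + theta * (ratio @ phi.T)
        theta = gamma / gamma.sum(axis=1, keepdims=True)
    return theta


def fit_topic_model(
    docs: list[list[str]],
    k: int,
    alpha: float | None = None,
    eta: float = 0.01,
    seed: int = 0,
    max_iter: int = 25,
) -> TopicModel:
    """Fit a k-topic LDA on tokenized documents; deterministic given seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(docs) < k:
        raise ValueError(f"need at least k={k} documents, got {len(docs)}")
    a = (1.0 / k) if alpha is None else float(alpha)
    X, words = _build_counts(docs)
    lda = LatentDirichletAllocation(
        n_components=k,
        doc_topic_prior=a,
        topic_word_prior=eta,
        learning_method="batch",
        max_iter=max_iter,
        random_state=int(seed) % (2**31),
        evaluate_every=-1,
    )
    lda.fit(X)
    topic_word = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    model = TopicModel(
        k=k, vocab=words, topic_word=topic_word,
        doc_topic=np.zeros((len(docs), k)), alpha=a, eta=eta, seed=int(seed),
    )
    model.doc_topic = _fold_in(topic_word, X, a)
    return model


def perplexity(model: TopicModel, holdout: list[list[str]]) -> float:
    """Held-out perplexity exp(-sum log p(d) / sum l) with per-token
    predictive probability theta_d . phi[:, w]; out-of-vocabulary tokens are
    excluded from both sums.

    p(d) is estimated by symmetrized document completion: the mixture
    theta_d is inferred from the tokens at even positions and the likelihood
    evaluated on the tokens at odd positions, then the roles are swapped and
    both half-scores pooled — so a model with spurious extra topics cannot
    raise its score by fitting the very tokens it is judged on.  Records too
    short to split fall back to whole-document fold-in.
    """
    if not holdout:
        raise ValueError("holdout must be nonempty")
    est_rows, eval_rows = [], []
    for doc in holdout:
        est, evl = doc[0::2], doc[1::2]
        v_est = model.counts_vector(est)
        v_evl = model.counts_vector(evl)
        if v_est.sum() == 0 or v_evl.sum() == 0:
            whole = model.counts_vector(doc)
            est_rows.append(whole)
            eval_rows.append(whole)
        else:
            est_rows.append(v_est)
            eval_rows.append(v_evl)
            est_rows.append(v_evl)
            eval_rows.append(v_est)
    X_est = sparse.csr_matrix(np.vstack(est_rows))
    X_eval = sparse.csr_matrix(np.vstack(eval_rows))
    total_tokens = float(X_eval.sum())
    if total_tokens == 0:
        raise ValueError("holdout shares no vocabulary with the model")
    theta = _fold_in(model.topic_word, X_est, model.alpha)
    P = theta @ np.clip(model.topic_word, TOKEN_FLOOR, None)
    np.clip(P, TOKEN_FLOOR, None, out=P)
    loglik = float(X_eval.multiply(np.log(P)).sum())
    return math.exp(-loglik / total_tokens)


def select_child_count(
    docs: list[list[str]],
    k_range: tuple[int, int],
    holdout_fraction: float = 0.1,
    seed: int = 0,
    alpha: float | None = None,
    eta: float = 0.01,
    max_iter: int = 25,
) -> PerplexityReport:
    """Fit one model per k on a train split, evaluate perplexity on the
    holdout split, return the full table and the argmin (ties -> smaller k)."""
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo > k_hi:
        raise ValueError("empty k range")
    if len(docs) < 4:
        raise ValueError("need at least 4 documents to select a child count")
    if k_hi > len(docs):
        raise ValueError("k range exceeds the number of documents")
    rng = np.random.default_rng(stage_seed(seed, "holdout-split"))
    n = len(docs)
    m = max(1, math.ceil(holdout_fraction * n))
    hold_idx = set(rng.choice(n, size=m, replace=False).tolist())
    train = [d for i, d in enumerate(docs) if i not in hold_idx]
    hold = [docs[i] for i in sorted(hold_idx)]
    if len(train) < k_hi:
        k_hi = max(k_lo, len(train))
    table: list[tuple[int, float]] = []
    for k in range(k_lo, k_hi + 1):
        model = fit_topic_model(
            train, k, alpha=alpha, eta=eta,
            seed=stage_seed(seed, "lda", k), max_iter=max_iter,
        )
        table.append((k, perplexity(model, hold)))
    best = min(p for _, p in table)
    selected = min(k for k, p in table if p == best)
    return PerplexityReport(table=table, selected_k=selected)


def infer_mixture(model: TopicModel, record: QARecord | list[str]) -> np.ndarray:
    """Posterior topic mixture of one record; OOV tokens ignored; a record
    with no in-vocabulary tokens gets the uniform prior mixture."""
    tokens = record.tokens if isinstance(record, QARecord) else list(record)
    counts = model.counts_vector(tokens)
    if counts.sum() == 0:
        return np.full(model.k, 1.0 / model.k)
    theta = _fold_in(model.topic_word, counts[None, :], model.alpha)[0]
    return theta / theta.sum()
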