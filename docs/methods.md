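# Methods

This note records the modeling choices behind `medhier`: the procedure, its
assumptions, the parameters that matter, what the synthetic generator does
and does not emulate, and the numerical decisions taken where the design was
open.

## The organization model

The corpus is modeled as a mixture of latent topics arranged in a rooted
tree.  Three assumptions drive the design:

* **High-level categories are prior knowledge.**  Top-level health
  categories (e.g. "women's health", "mental health") overlap and correlate;
  extracting them from data is unreliable, while user-facing taxonomies
  capture them well.  The first layer is therefore supervised: per-category
  binary linear SVMs over weighted term bags, trained on seed example
  records, positives vs an equal-size seeded sample of the other categories'
  positives.  Records firing no classifier go to the best-scoring category so
  the first layer always covers the corpus; multi-membership is allowed when
  several classifiers fire (single-membership is a config switch).
* **Below the first layer, topics are discoverable by LDA.**  Each node's
  children are the components of an LDA model (batch variational inference,
  symmetric priors α = 1/k, η = 0.01) fitted on its members.  The child
  count is chosen by held-out perplexity over k ∈ [k_min, k_max]
  (default [2, 12]; ties break to the smaller k).
* **Expansion must terminate on homogeneous nodes.**  A fixed depth would
  force all branches to equal granularity; instead each node is trially
  bipartitioned by a 2-topic model, and the normalized inter-node relation
  of the two halves decides.  For statistically identical halves the
  relation approaches 2 (each cross-average equals each half-to-whole
  average); for separable halves it approaches 0.

### Perplexity estimation

Held-out record likelihood p(d) in the perplexity formula is estimated by
**symmetrized document completion**: the topic mixture θ_d is inferred by a
fixed-point fold-in from the tokens at even positions, the likelihood is
evaluated on the tokens at odd positions, the roles are swapped, and both
half-scores are pooled.  Plain fold-in (inferring θ_d from the same tokens
that are scored) lets a model with spurious extra topics fit the evaluation
tokens themselves; the perplexity curve then plateaus past the true child
count and the argmin drifts high.  With completion the curve turns flat-to-up
at the planted count and the argmin recovers it (the recovery test plants 4
children in 2000 records and finds k ∈ {3,4,5} in ≥ 8 of 10 seeds).
Out-of-vocabulary tokens are excluded from both numerator and denominator;
per-token probabilities are floored at 1e-12.  Note the perplexity exponent
carries the minus sign of the standard definition, so that lower is better.

### Record assignment

Records are assigned to the **leading children** of their posterior mixture:
sort descending, cut at the first maximal adjacent gap, keep everything
before the cut.  Consequences worth knowing: a 2-child posterior has a single
gap, so dual assignment requires nodes with ≥ 3 children; an all-equal
posterior keeps only the top child (tie rule).  Children cover their parent
by construction; empty children are dropped, and a node whose assignment
collapses to fewer than 2 nonempty children reverts to a leaf.

### Node profiling

Noun phrases are token spans whose POS classes match
`(Adj|Noun)* (Noun Prep)? (Adj|Noun)* Noun`, extracted as maximal
non-overlapping matches, singularized by a small rule table (no lemmatizer;
`-ches` is treated as a sibilant plural only after a consonant, so
"branches" → "branch" but "headaches" → "headache").  The top-k frequent
phrases (default k = 20) each cast one binary vote for the terminology their
lexicon entry names; terminologies are ranked by votes, then summed phrase
frequency, then id, and the top 5 become the node's labels.  The lexicon is
an exact-match table after lowercasing/singularization — a deliberate
stand-in for a metathesaurus mapper behind a narrow interface (`lookup`),
so a real service can be plugged in.

## Similarity kernels

* **Φ1, weighted term kernel**: cosine over term-count bags; a term whose
  lexicon entry falls in a boosted semantic group (defaults: disease or
  syndrome; body part, organ, or organ component; sign or symptom; neoplasm)
  is multiplied once by the boost factor (default 2.0).
* **Φ2, subset-tree kernel**: the number of parse fragments shared by two
  trees, by the standard subset-tree recursion with no decay, summed over
  all sentence pairs of two records and divided by the product of their
  sentence counts.  The bundled parser builds right-branching trees over POS
  tags; for such chains the recursion collapses to a vectorized backward
  recurrence (property-tested equal to the generic recursion and to
  exhaustive fragment enumeration).  Φ2 is unbounded, so its raw values are
  min–max scaled into [0, 1] over the record set at hand before fusion.
* **Φ3, topic kernel**: Jensen–Shannon divergence (natural log, bounded by
  ln 2) between topic mixtures in a single corpus-level topic space whose
  dimension is itself selected by perplexity at build time.  A corpus-level
  space (rather than per-node models) keeps mixtures comparable across any
  candidate set met during shrinkage or retrieval.
* **Fusion**: Φ = β₁Φ1 + β₂Φ2 + β₃(1 − Φ3/ln 2).  The divergence is
  converted to a similarity so all three components point the same way; the
  raw-divergence polarity remains selectable in config.  Defaults
  β = (0.6, 0.1, 0.3) weight the lexical signal highest, keep a small
  syntactic contribution, and give the topic signal enough mass to bridge
  vocabulary gaps; the 0.05-step simplex grid used for tuning is exposed as
  `SimilarityWeights.grid()`.

## Shrinkage calibration

δ is an empirical threshold by nature.  Two regimes emerge on generated
corpora: trial bipartitions of homogeneous nodes give inter ≈ 1.9 (theory: 2
for identical halves, minus finite-size effects), while bipartitions that
cleanly separate planted sibling topics give 1.3–1.6 — not lower, because
realistic siblings share their parent's vocabulary and concept phrases.  The
default δ = 1.7 sits between the regimes; `inter == δ` still expands
(termination requires strictly greater).  Equation-level conventions:
S(x, x) = 1 for the identity pairs the literal cross-product averages
include, and the similarity feeding the averages is the fused kernel with Φ2
scaled over the node's (sub)pool.

Because the averages are O(n²) in node size, nodes larger than
`shrinkage_sample` (default 100) are subsampled with a seeded draw before the
statistics are computed; the statistics are means, so subsampling changes
variance, not expectation.

## Retrieval

Routing descends the tree: classifiers choose first-layer categories, the
node-level topic mixtures and the leading-children rule choose below.  A
query with no usable tokens routes to every first-layer node with a warning.
Pooled leaf members get initial scores ȳ from the fused kernel; the pool is
capped at `rerank_pool` (default 150) strongest initial matches before the
O(n²) similarity graph is built.  The reranking recurrence
y ← 1/(1+λ)·W D⁻¹ y + λ/(1+λ)·ȳ is a contraction for λ > 0 (the iteration
matrix has spectral radius ≤ 1/(1+λ)); iteration stops at max-norm change
< 1e-8 or 500 iterations, and agrees with the direct linear solve to 1e-6.
Isolated candidates (zero similarity row) keep their initial scores.

**λ default 9.** The model's second assumption states the final relevance
probabilities should stay close to the initialized ones, and λ/(1+λ) is the
weight the fixed point gives them.  λ = 9 (weight 0.9) honors that
assumption and empirically keeps an exact query match ranked first while the
remaining 10% of graph smoothing still lifts same-topic paraphrase targets;
small λ (e.g. 0.1) hands 90% of the weight to graph structure and the
ranking degenerates toward graph centrality, dropping even exact matches from
the top ranks.  λ is exposed in config and on the CLI.

## Synthetic data: what it emulates, and what it does not

The generator plants a topic tree with configured branching.  Each topic owns
a private vocabulary block; a leaf draws 80% of its mass from its own block,
10% from its parent's, 10% from a global shared block (the shared fraction is
configurable; at 0 sibling supports are disjoint).  Records are short (mean
30 tokens, negative-binomial lengths), split into question/answer/tags; at
the mixture rate (default 0.2) a record blends two sibling leaves 50/50 and
carries both memberships.  Every topic has a planted terminology with three
surface variants (one plural); variants are injected into the member records
— the leaf concept into the question (rate 0.8), ancestor concepts into the
answer (rate 0.5) — behind a verb-tagged connector so the phrase matcher sees
them as delimited noun phrases.  The lexicon maps the variants (and the
concept words) to the terminology; the reference taxonomy mirrors the true
tree.  Queries take a pure record's question and substitute a fraction of
tokens (default 0.5) via a fixed-point-free synonym table that rotates words
within their topic block, so substitutes are real same-topic words; an
"alias" table of out-of-vocabulary substitutes is available for stress tests.
Graded gains: 2 for the source record, 1 for same-leaf records, 0 otherwise.

What this does **not** emulate: real medical language (tokens are synthetic
symbols), polysemy and sense ambiguity, tagger/parser noise, answer quality
variation, spelling errors, or the scale of a production crawl.  Passing
tests therefore demonstrate that each stage recovers the structure it assumes
when that structure is present — not performance on real clinical text.

## Problem sizes and determinism

The bundled tests and the acceptance script run at desk scale: corpora of
160–2000 records, k-ranges capped at 6–8, 50 queries.  These sizes were
chosen so the statistical checks (child-count recovery, assignment
precision/recall, NDCG comparisons) have adequate signal while the full
pipeline stays in the tens of seconds.  A single global seed is expanded into
per-stage seeds via CRC32-keyed `SeedSequence`s; every stage (LDA, SVM
negatives, subsampling, generation) derives from it, so a rerun with the same
seed reproduces hierarchy stores and search outputs byte for byte.

## Known limitations

* The shrinkage decision rests on one trial bipartition; a multi-restart
  consensus would be more stable on borderline nodes.
* Tuple accuracy and cohesiveness depend on how many labels per node enter
  the computation (defaults: top-1 for tuples, all stored labels for
  cohesiveness, both configurable); the pooling is global across adjacent
  pairs, with per-pair averaging available as an alternative reading.
* The bundled tagger/parser are deliberately minimal; Φ2 with right-branching
  trees is a tagged-sequence kernel, not true constituency similarity.
* Records are assigned once during construction; there is no re-assignment
  after the hierarchy is complete, and no incremental insertion.
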