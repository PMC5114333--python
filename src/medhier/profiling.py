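"""Node profiling: label hierarchy nodes with ranked standard terminologies.

For each node, every member record's text is POS-tagged and all maximal token
spans matching the noun-phrase pattern

    (Adjective | Noun)* (Noun Preposition)? (Adjective | Noun)* Noun

are extracted (e.g. "ineffective treatment of terminal lung cancer").  Plural
variants are singularized and merged.  The top-k frequent phrases are then
normalized to standard terminologies through the concept lexicon, each phrase
casting one binary vote for the terminology it maps to; distinct phrases like
"painful neck" and "neck ache" that normalize to the same terminology
accumulate its score.  The top-scoring terminologies become the node labels.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .lexicon import ConceptLexicon, singularize_phrase
from .nlp import PosTagger, tokenize_words

__all__ = [
    "PhraseCandidates",
    "TerminologyScores",
    "extract_noun_phrases",
    "vote_terminologies",
    "label_node",
    "NodeLabel",
]

log = logging.getLogger(__name__)

# tag-class characters: A adjective, N noun, P preposition, O other
_TAG_CLASS = {"adjective": "A", "noun": "N", "preposition": "P"}
_NP_RE = re.compile(r"[AN]*(?:NP)?[AN]*N")


@dataclass
class PhraseCandidates:
    """Top-k frequent noun phrases with counts, non-increasing."""

    phrases: list[tuple[str, int]]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.phrases]
        if any(c2 > c1 for c1, c2 in zip(counts, counts[1:])):
            raise ValueError("candidate counts must be non-increasing")


@dataclass
class TerminologyScores:
    """terminology id -> vote score, with ranking metadata."""

    scores: dict[str, int]
    ranked: list[tuple[str, str, int]]  # (term id, term name, score), best first


@dataclass(frozen=True)
class NodeLabel:
    term_id: str
    term_name: str
    score: int


def _tag_class(tag: str) -> str:
    return _TAG_CLASS.get(tag.lower(), "O")


def extract_noun_phrases(
    texts: Iterable[str], tagger: PosTagger
) -> Counter[str]:
    """All maximal noun-phrase matches over the texts, singularized, counted."""
    counts: Counter[str] = Counter()
    for text in texts:
        tokens = tokenize_words(text)
        if not tokens:
            continue
        try:
            tags = tagger.tag(tokens)
        except Exception:  # noqa: BLE001 - a failing tagger skips the text
            log.warning("tagger failed on text %r...; skipped", text[:40])
            continue
        if len(tags) != len(tokens):
            log.warning("tagger returned %d tags for %d tokens; text skipped", len(tags), len(tokens))
            continue
        classes = "".join(_tag_class(t) for t in tags)
        for m in _NP_RE.finditer(classes):
            if m.end() <= m.start():
                continue
            phrase = " ".join(tokens[m.start() : m.end()])
            counts[singularize_phrase(phrase)] += 1
    return counts


def top_phrases(counts: Counter[str], k: int) -> PhraseCandidates:
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return PhraseCandidates(list(ranked))


def vote_terminologies(
    candidates: PhraseCandidates, lexicon: ConceptLexicon
) -> TerminologyScores:
    """Binary voting: score(t) = number of candidate phrases normalizing to t.

    Phrases with no lexicon entry cast no vote.  Ranking: score descending,
    ties by summed phrase frequency, then lexicographic terminology id.
    """
    if not candidates.phrases:
        raise ValueError("no candidate phrases to vote on")
    scores: dict[str, int] = {}
    freq: dict[str, int] = {}
    names: dict[str, str] = {}
    for phrase, count in candidates.phrases:
        entry = lexicon.lookup(phrase)
        if entry is None:
            continue
        scores[entry.term_id] = scores.get(entry.term_id, 0) + 1
        freq[entry.term_id] = freq.get(entry.term_id, 0) + count
        names[entry.term_id] = entry.term_name
    if not scores:
        log.warning("no candidate phrase maps to any terminology")
        return TerminologyScores(scores={}, ranked=[])
    ranked_ids = sorted(scores, key=lambda t: (-scores[t], -freq[t], t))
    ranked = [(t, names[t], scores[t]) for t in ranked_ids]
    return TerminologyScores(scores=scores, ranked=ranked)


def label_node(
    member_texts: Sequence[str],
    lexicon: ConceptLexicon,
    tagger: PosTagger,
    k: int = 20,
    top_n: int = 5,
) -> list[NodeLabel]:
    """Extract phrases over a node's member texts, vote, return top labels."""
    if not member_texts:
        raise ValueError("cannot label a node with no member texts")
    counts = extract_noun_phrases(member_texts, tagger)
    candidates = top_phrases(counts, k)
    if not candidates.phrases:
        return []
    votes = vote_terminologies(candidates, lexicon)
    return [NodeLabel(t, name, s) for t, name, s in votes.ranked[:top_n]]
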