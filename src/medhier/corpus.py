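"""QA records and corpora: the data model, JSONL I/O, and contextualization.

A *QA record* is one community-health question together with the answers and
tags posted for it.  Questions alone are short and give too little word
co-occurrence for similarity estimation, so each record is *contextualized*:
its token sequence is the normalized question tokens followed by answer tokens
followed by tag tokens.  Incoming search queries, by contrast, carry only a
question part.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "QARecord",
    "Corpus",
    "TokenNormalizer",
    "read_corpus",
    "write_corpus",
    "contextualize",
    "split_holdout",
    "CorpusParseError",
]


class CorpusParseError(ValueError):
    """A malformed corpus file; carries the offending line number."""


_TOKEN_RE = re.compile(r"[a-z0-9]+(?:'[a-z]+)?")


class TokenNormalizer:
    """Lowercase, split on punctuation/whitespace, drop stop-words."""

    def __init__(self, stopwords: Iterable[str] = ()) -> None:
        self.stopwords = frozenset(w.lower() for w in stopwords)

    def __call__(self, text: str) -> list[str]:
        return [t for t in _TOKEN_RE.findall(text.lower()) if t not in self.stopwords]


@dataclass
class QARecord:
    """One health QA item.  ``tokens``/``length`` are filled by contextualize."""

    id: str
    question: str
    answers: list[str] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)
    tokens: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.tokens)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "question": self.question,
            "answers": list(self.answers),
            "tags": list(self.tags),
        }

    def sentences(self) -> list[str]:
        """Sentence-level view used by the syntactic kernel: the question,
        each answer, and the tag list each count as one sentence."""
        out = [self.question]
        out.extend(a for a in self.answers if a.strip())
        if self.tags:
            out.append(" ".join(self.tags))
        return out


@dataclass
class Corpus:
    records: list[QARecord]
    holdout_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise CorpusParseError(f"duplicate record id {i!r}")
                seen.add(i)
        unknown = self.holdout_ids - set(ids)
        if unknown:
            raise ValueError(f"holdout ids not in corpus: {sorted(unknown)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[QARecord]:
        return iter(self.records)

    def __getitem__(self, rid: str) -> QARecord:
        return self.by_id[rid]

    @property
    def by_id(self) -> dict[str, QARecord]:
        cache = getattr(self, "_by_id", None)
        if cache is None or len(cache) != len(self.records):
            cache = {r.id: r for r in self.records}
            object.__setattr__(self, "_by_id", cache)
        return cache

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def train_ids(self) -> list[str]:
        return [r.id for r in self.records if r.id not in self.holdout_ids]


def read_corpus(path: str | Path) -> Corpus:
    """Read a JSONL corpus (one object per line: id, question, answers, tags).

    Raises :class:`CorpusParseError` naming the line number on malformed input.
    """
    records: list[QARecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            if not isinstance(obj, dict) or "id" not in obj or "question" not in obj:
                raise CorpusParseError(f"line {lineno}: object must carry 'id' and 'question'")
            records.append(
                QARecord(
                    id=str(obj["id"]),
                    question=str(obj["question"]),
                    answers=[str(a) for a in obj.get("answers", []) or []],
                    tags=[str(t) for t in obj.get("tags", []) or []],
                )
            )
    return Corpus(records)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus.records:
            fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")


def contextualize(
    record: QARecord,
    normalizer: TokenNormalizer | None = None,
    keep_all_answers: bool = True,
) -> list[str]:
    """Fill ``record.tokens`` with question + answer + tag tokens, normalized.

    Order is contractual: question tokens first, then answers (in posted
    order), then tags.  Idempotent: reprocessing yields identical tokens.
    """
    if not record.question or not record.question.strip():
        raise ValueError(f"record {record.id!r} has an empty question")
    norm = normalizer or TokenNormalizer()
    answers = record.answers if keep_all_answers else record.answers[:1]
    tokens = norm(record.question)
    for ans in answers:
        tokens.extend(norm(ans))
    for tag in record.tags:
        tokens.extend(norm(tag))
    record.tokens = tokens
    return tokens


def contextualize_corpus(
    corpus: Corpus,
    normalizer: TokenNormalizer | None = None,
    keep_all_answers: bool = True,
) -> Corpus:
    for rec in corpus.records:
        contextualize(rec, normalizer, keep_all_answers)
    return corpus


def split_holdout(corpus: Corpus, fraction: float, seed: int) -> Corpus:
    """Mark ceil(fraction*n) records as perplexity hold-out, seeded, in place."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(corpus.records)
    if n < 2:
        raise ValueError("corpus needs at least 2 records to split")
    m = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=m, replace=False)
    corpus.holdout_ids = {corpus.records[i].id for i in idx}
    return corpus
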