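"""Pluggable POS tagging and sentence parsing, with bundled toy implementations.

Production deployments would plug a trained tagger and a constituency parser
in behind these two interfaces; the bundled defaults — a lexicon-based tagger
and a right-branching parser over POS tags — keep the whole pipeline runnable
offline and deterministic, which is what the tests and the synthetic fixtures
exercise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

__all__ = [
    "PosTagger",
    "LexiconPosTagger",
    "SentenceParser",
    "RightBranchingParser",
    "ParseTree",
    "tokenize_words",
]

_WORD_RE = re.compile(r"[A-Za-z0-9']+")


def tokenize_words(text: str) -> list[str]:
    return [w.lower() for w in _WORD_RE.findall(text)]


class PosTagger(Protocol):
    """token list in -> one tag per token out."""

    def tag(self, tokens: Sequence[str]) -> list[str]: ...


class LexiconPosTagger:
    """Word -> tag table with a default tag for unknown words.

    Tags are coarse category names ("Noun", "Adjective", "Preposition",
    "Verb", ...); the noun-phrase pattern matcher only distinguishes
    adjective/noun/preposition from everything else.
    """

    def __init__(self, table: dict[str, str] | None = None, default: str = "Noun") -> None:
        self.table = {k.lower(): v for k, v in (table or {}).items()}
        self.default = default

    def tag(self, tokens: Sequence[str]) -> list[str]:
        return [self.table.get(t.lower(), self.default) for t in tokens]

    @classmethod
    def read_tsv(cls, path: str | Path, default: str = "Noun") -> "LexiconPosTagger":
        table: dict[str, str] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                word, tag = line.split("\t")
                table[word] = tag
        return cls(table, default=default)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for word in sorted(self.table):
                fh.write(f"{word}\t{self.table[word]}\n")


@dataclass(frozen=True)
class ParseTree:
    """Rooted ordered tree: internal nodes carry nonterminal labels, leaves
    carry tokens.  Frozen/hashable so kernel computations can be cached."""

    label: str
    children: tuple["ParseTree", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_preterminal(self) -> bool:
        return bool(self.children) and all(c.is_leaf for c in self.children)

    def internal_nodes(self) -> list["ParseTree"]:
        out: list[ParseTree] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.children:
                out.append(node)
                stack.extend(node.children)
        return out

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def production(self) -> tuple[str, tuple[str, ...]]:
        return (self.label, tuple(c.label for c in self.children))

    def validate(self) -> None:
        for node in self.internal_nodes():
            if not node.children:
                raise ValueError("internal node without children")
            for c in node.children:
                if c.is_leaf and c.label == "":
                    raise ValueError("empty leaf token")


class SentenceParser(Protocol):
    def parse(self, sentence: str) -> ParseTree: ...


class RightBranchingParser:
    """Toy parser: preterminal (TAG token) nodes chained right-branching under S.

    The tree for tokens t1..tn is S(P1, S(P2, S(... ))), with Pi the
    preterminal for ti.  Structure is fully determined by the tagged token
    sequence, which makes the tree kernel a (structure-aware) sequence kernel
    — adequate as an offline stand-in for a constituency parser.
    """

    def __init__(self, tagger: PosTagger | None = None) -> None:
        self.tagger = tagger or LexiconPosTagger()

    def parse(self, sentence: str) -> ParseTree:
        tokens = tokenize_words(sentence)
        if not tokens:
            raise ValueError("cannot parse an empty sentence")
        tags = self.tagger.tag(tokens)
        preterms = [ParseTree(tag, (ParseTree(tok),)) for tag, tok in zip(tags, tokens)]
        tree = ParseTree("S", (preterms[-1],))
        for pre in reversed(preterms[:-1]):
            tree = ParseTree("S", (pre, tree))
        return tree
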