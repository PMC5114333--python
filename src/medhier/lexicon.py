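"""Concept lexicon: surface phrase -> standard terminology mapping.

This is the package's abstraction of a medical metathesaurus lookup
(UMLS/MetaMap in production): an exact-match table from normalized surface
phrases to terminology entries carrying a semantic group.  Lookup is
case-insensitive after rule-based singularization, so plural surface variants
("headaches") normalize to the same terminology as their singular form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = ["TermEntry", "ConceptLexicon", "singularize", "singularize_phrase"]

# suffix rules applied in order; first match wins
_PLURAL_RULES: tuple[tuple[str, str], ...] = (
    ("ies", "y"),
    ("shes", "sh"),
    ("sses", "ss"),
    ("xes", "x"),
    ("zes", "z"),
    ("oes", "o"),
    ("s", ""),
)

_VOWELS = "aeiou"


def singularize(word: str) -> str:
    """Rule-table singularization (no lemmatizer): strip plural suffixes."""
    w = word.lower()
    if len(w) <= 3 or w.endswith("ss") or w.endswith("us") or w.endswith("is"):
        return w
    # sibilant -ches (branches -> branch) only after a consonant; a vowel
    # before "ches" marks an -e stem plus plural s (aches -> ache)
    if w.endswith("ches") and len(w) > 5 and w[-5] not in _VOWELS:
        return w[:-2]
    for suffix, repl in _PLURAL_RULES:
        if w.endswith(suffix) and len(w) > len(suffix) + 1:
            return w[: -len(suffix)] + repl
    return w


def singularize_phrase(phrase: str) -> str:
    return " ".join(singularize(tok) for tok in phrase.lower().split())


@dataclass(frozen=True)
class TermEntry:
    term_id: str
    term_name: str
    semantic_group: str


class ConceptLexicon:
    """Phrase -> terminology table; many phrases may map to one terminology."""

    def __init__(self, entries: Iterable[tuple[str, TermEntry]] = ()) -> None:
        self._map: dict[str, TermEntry] = {}
        self._ids: dict[str, TermEntry] = {}
        for phrase, entry in entries:
            self.add(phrase, entry)

    def add(self, phrase: str, entry: TermEntry) -> None:
        key = singularize_phrase(phrase)
        self._map[key] = entry
        prev = self._ids.get(entry.term_id)
        if prev is not None and prev != entry:
            raise ValueError(f"terminology id {entry.term_id!r} mapped inconsistently")
        self._ids[entry.term_id] = entry

    def lookup(self, phrase: str) -> TermEntry | None:
        return self._map.get(singularize_phrase(phrase))

    def lookup_word_group(self, word: str) -> str | None:
        """Semantic group of a single-word concept, for term-kernel boosting."""
        entry = self._map.get(singularize(word))
        return entry.semantic_group if entry is not None else None

    def entry_for_id(self, term_id: str) -> TermEntry | None:
        return self._ids.get(term_id)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, phrase: str) -> bool:
        return self.lookup(phrase) is not None

    def phrases(self) -> list[str]:
        return sorted(self._map)

    # -- TSV I/O: phrase <TAB> term id <TAB> term name <TAB> semantic group --
    @classmethod
    def read_tsv(cls, path: str | Path) -> "ConceptLexicon":
        lex = cls()
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
                phrase, tid, tname, group = parts
                lex.add(phrase, TermEntry(tid, tname, group.lower()))
        return lex

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for phrase in sorted(self._map):
                e = self._map[phrase]
                fh.write(f"{phrase}\t{e.term_id}\t{e.term_name}\t{e.semantic_group}\n")
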