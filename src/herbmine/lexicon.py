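"""Tagging dictionaries of formula, herb, and adjunct terms.

A lexicon maps surface terms (unsegmented Chinese strings, NFC-normalized)
to one of three categories:

``formula``
    a named multi-herb prescription (e.g. 茯苓補心湯);
``herb``
    an individual medicinal ingredient (e.g. 甘草);
``adjunct``
    a non-therapeutic processing substance co-listed with herbs
    (honey 蜜, vinegar 醋).

Lexicons from several sources are combined by set union with duplicate
exclusion; on a category conflict the more specific category wins
(formula > herb > adjunct) and the conflict is logged.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

CATEGORIES = ("formula", "herb", "adjunct")
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


@dataclass(frozen=True)
class LexiconEntry:
    """One surface term of the tagging dictionary."""

    term: str
    category: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.term:
            raise ValueError("lexicon term must be non-empty")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not one of {CATEGORIES}"
            )
        object.__setattr__(self, "term", _nfc(self.term))
        object.__setattr__(self, "aliases", tuple(_nfc(a) for a in self.aliases))


class Lexicon:
    """An ordered, term-unique collection of :class:`LexiconEntry`."""

    def __init__(self, entries: Iterable[LexiconEntry] = ()) -> None:
        self._entries: dict[str, LexiconEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: LexiconEntry) -> None:
        """Insert an entry; duplicate terms keep the higher-priority category."""
        old = self._entries.get(entry.term)
        if old is None:
            self._entries[entry.term] = entry
            return
        if old.category != entry.category:
            winner = min(old, entry, key=lambda e: _PRIORITY[e.category])
            logger.warning(
                "category conflict for %r: %s vs %s -> kept %s",
                entry.term, old.category, entry.category, winner.category,
            )
        else:
            winner = old
        aliases = tuple(dict.fromkeys(old.aliases + entry.aliases))
        self._entries[entry.term] = LexiconEntry(entry.term, winner.category, aliases)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, term: str) -> bool:
        return _nfc(term) in self._entries

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Lexicon):
            return NotImplemented
        return self._entries == other._entries

    def get(self, term: str) -> LexiconEntry | None:
        return self._entries.get(_nfc(term))

    def category(self, term: str) -> str:
        return self._entries[_nfc(term)].category

    @property
    def terms(self) -> set[str]:
        return set(self._entries)

    def terms_of(self, *categories: str) -> list[str]:
        """Terms of the given categories, in insertion order."""
        return [e.term for e in self if e.category in categories]

    def terms_by_length(self) -> list[str]:
        """Terms sorted longest-first (ties lexicographic) for greedy tagging."""
        return sorted(self._entries, key=lambda t: (-len(t), t))

    # -- set algebra ---------------------------------------------------------
    def union(self, *others: "Lexicon") -> "Lexicon":
        merged = Lexicon(self)
        for lex in others:
            for e in lex:
                merged.add(e)
        return merged

    def intersect(self, other: "Lexicon") -> "Lexicon":
        """Terms present in both lexicons; categories taken from *self*."""
        return Lexicon(e for e in self if e.term in other)

    # -- TSV serialization: term TAB category TAB comma-joined-aliases -------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        lex = cls()
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected term<TAB>category")
            term, category = parts[0], parts[1]
            aliases = tuple(a for a in parts[2].split(",") if a) if len(parts) > 2 else ()
            lex.add(LexiconEntry(term, category, aliases))
        return lex

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{e.term}\t{e.category}\t{','.join(e.aliases)}" for e in self
        ]
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def union_merge(*lexicons: Lexicon) -> Lexicon:
    """Set-union several lexicons, excluding duplicate terms.

    Category conflicts resolve formula > herb > adjunct and are logged.
    """
    if not lexicons:
        raise ValueError("union_merge needs at least one lexicon")
    return lexicons[0].union(*lexicons[1:])


def intersect_lexicons(a: Lexicon, b: Lexicon) -> Lexicon:
    """Terms present in both *a* and *b*, with categories from *a*.

    This is the candidate-filtering step that restricts mined herb terms to
    a reference herb-name list (e.g. a curated database of herb names).
    """
    return a.intersect(b)
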