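"""Entity extraction from classical-style formula entries.

Two complementary mechanisms:

1. **Structural patterns** — regular expressions matching the recurring
   shapes of formula entries in classical formularies: an herb token
   followed by a parenthesized preparation/dosage note (乾薑(炮)), a
   symptom line of the form 治…方, a formula name ending in 湯 followed
   by a 治… indication block, and one-line or two-line 治…用… entries.

2. **Dictionary tagging** — a greedy, left-to-right, longest-match-first
   scan against a lexicon.  Classical Chinese has no word separators, so
   matching operates on the raw character sequence; sorting terms by
   descending length prevents re-segmentation: once a span is tagged its
   characters cannot participate in another match.

An iterative loop combines both: patterns propose candidate terms, a
plain-text review list stands in for interactive curation, accepted terms
are union-merged into the lexicon, and the corpus is re-tagged until no
new terms are accepted.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .lexicon import Lexicon, LexiconEntry, intersect_lexicons, union_merge

__all__ = [
    "PatternSpec",
    "TaggedSpan",
    "AnnotatedEntry",
    "Transaction",
    "UnbalancedParenthesesWarning",
    "compile_patterns",
    "extract_herb_preparations",
    "tag_text",
    "propose_candidates",
    "iterate_extraction",
    "build_transactions",
    "union_merge",
    "intersect_lexicons",
    "read_transactions_tsv",
    "write_transactions_tsv",
]

# CJK unified ideographs (base + ext A) — the character class of herb tokens.
_CJK = r"㐀-鿿"
# Both full-width （） and half-width () parentheses occur in the sources.
_OPEN = "（("
_CLOSE = "）)"


class UnbalancedParenthesesWarning(UserWarning):
    """An entry contained an opening parenthesis with no closing one."""


@dataclass(frozen=True)
class PatternSpec:
    """A structural pattern and the entry role it extracts."""

    pattern_id: str
    expression: str
    target_role: str

    @property
    def regex(self) -> re.Pattern[str]:
        return re.compile(self.expression, re.MULTILINE)


def compile_patterns() -> list[PatternSpec]:
    """The five structural entry patterns.

    ``herb_preparation`` captures the herb surface form and the
    parenthesized preparation/dosage text as separate groups.
    """
    return [
        PatternSpec(
            "herb_preparation",
            rf"([{_CJK}]{{1,10}}?)[{_OPEN}]([^{_OPEN}{_CLOSE}]*)[{_CLOSE}]",
            "herb+preparation",
        ),
        PatternSpec("symptom_prescription", r"治[^\n]*?方", "symptom"),
        PatternSpec(
            "formula_symptom",
            rf"([^\s{_OPEN}{_CLOSE}]{{1,12}}湯)\s*\n(治[^\n]*)",
            "formula+symptom",
        ),
        PatternSpec("symptom_usage_inline", r"治[^\n]*?用[^\n]*", "symptom+usage"),
        PatternSpec(
            "symptom_usage_multiline", r"治[^\n]*\n用[^\n]*", "symptom+usage"
        ),
    ]


def extract_herb_preparations(entry_text: str) -> list[tuple[str, str]]:
    """Split an herb-list line into (herb, preparation) pairs.

    Herb tokens are whitespace-delimited; a parenthesized annotation
    immediately following a token is its preparation/dosage note and is
    excluded from the herb term.  On an unbalanced parenthesis the entry
    is flagged with :class:`UnbalancedParenthesesWarning` and the pairs
    found before the defect are returned.
    """
    pairs: list[tuple[str, str]] = []
    for token in entry_text.split():
        opens = [i for i, ch in enumerate(token) if ch in _OPEN]
        if not opens:
            if token and all(ch not in _CLOSE for ch in token):
                pairs.append((token, ""))
            continue
        i = opens[0]
        herb = token[:i]
        rest = token[i + 1 :]
        j = next((k for k, ch in enumerate(rest) if ch in _CLOSE), None)
        if j is None:
            warnings.warn(
                f"unbalanced parenthesis in token {token!r}; entry flagged",
                UnbalancedParenthesesWarning,
                stacklevel=2,
            )
            return pairs
        if herb:
            pairs.append((herb, rest[:j]))
    return pairs


@dataclass(frozen=True)
class TaggedSpan:
    """A non-overlapping character span (0-based, half-open) with category."""

    start: int
    end: int
    term: str
    category: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("span must satisfy start < end")


def tag_text(entry_text: str, lexicon: Lexicon) -> list[TaggedSpan]:
    """Greedy left-to-right longest-match-first dictionary tagging.

    At each position the longest lexicon term starting there is tagged;
    the scan then resumes after the span, so tagged characters never
    participate in a second match.  Spans are returned in text order.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    terms = lexicon.terms
    max_len = max(len(t) for t in terms)
    spans: list[TaggedSpan] = []
    i, n = 0, len(entry_text)
    while i < n:
        for ln in range(min(max_len, n - i), 0, -1):
            cand = entry_text[i : i + ln]
            if cand in terms:
                spans.append(TaggedSpan(i, i + ln, cand, lexicon.category(cand)))
                i += ln
                break
        else:
            i += 1
    return spans


@dataclass
class AnnotatedEntry:
    """One corpus entry with its tagged spans and optional metadata."""

    entry_id: str
    text: str
    spans: list[TaggedSpan] = field(default_factory=list)
    phylum: str | None = None

    @property
    def formula(self) -> str | None:
        """First tagged formula term, if any."""
        for s in self.spans:
            if s.category == "formula":
                return s.term
        return None

    def terms_in_order(self, categories: Sequence[str]) -> list[str]:
        """Distinct tagged terms of *categories*, in first-appearance order."""
        return list(
            dict.fromkeys(s.term for s in self.spans if s.category in categories)
        )


def annotate_corpus(
    entries: Sequence[tuple[str, str]],
    lexicon: Lexicon,
    phyla: Mapping[str, str] | None = None,
) -> list[AnnotatedEntry]:
    """Tag every ``(entry_id, text)`` pair of a corpus."""
    phyla = phyla or {}
    return [
        AnnotatedEntry(eid, text, tag_text(text, lexicon), phyla.get(eid))
        for eid, text in entries
    ]


def propose_candidates(entry_text: str) -> dict[str, str]:
    """Candidate ``term -> category`` proposals from the structural patterns.

    Herb candidates come from parenthesized-preparation tokens and bare
    whitespace-delimited tokens on herb-list lines; formula candidates
    from 湯-suffixed name lines and 宜服…方 prescriptions.
    """
    cands: dict[str, str] = {}
    patterns = {p.pattern_id: p.regex for p in compile_patterns()}
    for m in patterns["formula_symptom"].finditer(entry_text):
        cands[m.group(1)] = "formula"
    for m in re.finditer(rf"宜服([{_CJK}]{{2,12}}?)方", entry_text):
        cands.setdefault(m.group(1), "formula")
    for line in entry_text.splitlines():
        if line.startswith("治") or line.endswith("湯"):
            continue  # symptom/name lines do not contribute herb tokens
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnbalancedParenthesesWarning)
            for herb, _prep in extract_herb_preparations(line):
                if re.fullmatch(rf"[{_CJK}]{{1,10}}", herb):
                    cands.setdefault(herb, "herb")
    return cands


def read_review_list(path: str | Path) -> dict[str, str]:
    """Read an accepted-terms review list: ``term<TAB>category`` per line."""
    accepted: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        accepted[parts[0].strip()] = parts[1].strip() if len(parts) > 1 else "herb"
    return accepted


def iterate_extraction(
    entries: Sequence[tuple[str, str]],
    seed_lexicon: Lexicon,
    review: Mapping[str, str] | str | Path | None = None,
    max_iterations: int = 10,
    phyla: Mapping[str, str] | None = None,
) -> tuple[list[AnnotatedEntry], Lexicon, list[dict]]:
    """Pattern-propose / review-accept / union-merge / re-tag loop.

    ``review`` is the scripted replacement for interactive curation: only
    candidate terms listed there are accepted into the lexicon.  The loop
    stops when an iteration accepts no new term, or at *max_iterations*.
    Returns the final annotation, the final lexicon, and a per-iteration
    report of proposed and accepted terms.
    """
    if isinstance(review, (str, Path)):
        review = read_review_list(review)
    review = dict(review or {})
    lexicon = union_merge(seed_lexicon)  # copy
    report: list[dict] = []
    ever_proposed: set[str] = set()
    for iteration in range(1, max_iterations + 1):
        proposed: dict[str, str] = {}
        for _eid, text in entries:
            for term, cat in propose_candidates(text).items():
                proposed.setdefault(term, cat)
        ever_proposed |= set(proposed)
        new = {
            t: review[t]
            for t in proposed
            if t in review and t not in lexicon
        }
        report.append(
            {"iteration": iteration, "proposed": len(proposed), "accepted": sorted(new)}
        )
        if not new:
            break
        lexicon = union_merge(
            lexicon, Lexicon(LexiconEntry(t, c) for t, c in new.items())
        )
    unknown = [t for t in review if t not in ever_proposed and t not in lexicon]
    for t in unknown:
        warnings.warn(f"review term {t!r} never proposed by any pattern; skipped")
    return annotate_corpus(entries, lexicon, phyla), lexicon, report


@dataclass(frozen=True)
class Transaction:
    """The itemset of one formula entry: its tagged herb/adjunct terms."""

    entry_id: str
    items: frozenset[str]
    ordered_items: tuple[str, ...] = ()
    phylum: str | None = None
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.ordered_items:
            object.__setattr__(self, "ordered_items", tuple(sorted(self.items)))
        if set(self.ordered_items) != set(self.items):
            raise ValueError("ordered_items must enumerate exactly `items`")


def build_transactions(
    annotated: Iterable[AnnotatedEntry], include_adjuncts: bool = True
) -> list[Transaction]:
    """One transaction per entry; entries tagging no herb are dropped.

    Items are the distinct herb (and, by default, adjunct) terms of the
    entry; ``ordered_items`` preserves first appearance in the text, the
    order consumed by the sequence generator.
    """
    cats = ("herb", "adjunct") if include_adjuncts else ("herb",)
    out: list[Transaction] = []
    for e in annotated:
        ordered = e.terms_in_order(cats)
        if not ordered:
            continue
        out.append(
            Transaction(e.entry_id, frozenset(ordered), tuple(ordered),
                        e.phylum, e.formula)
        )
    return out


# -- file formats -----------------------------------------------------------

def write_transactions_tsv(transactions: Iterable[Transaction], path: str | Path) -> None:
    """``entry_id TAB phylum TAB formula TAB comma-joined items`` (UTF-8)."""
    lines = [
        "\t".join(
            [t.entry_id, t.phylum or "", t.formula or "", ",".join(t.ordered_items)]
        )
        for t in transactions
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_transactions_tsv(path: str | Path) -> list[Transaction]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        eid, phylum, formula, items = (line.split("\t") + ["", "", ""])[:4]
        ordered = tuple(i for i in items.split(",") if i)
        out.append(
            Transaction(eid, frozenset(ordered), ordered, phylum or None,
                        formula or None)
        )
    return out


def write_annotated_json(annotated: Iterable[AnnotatedEntry], path: str | Path) -> None:
    payload = [
        {
            "entry_id": e.entry_id,
            "text": e.text,
            "phylum": e.phylum,
            "spans": [[s.start, s.end, s.term, s.category] for s in e.spans],
        }
        for e in annotated
    ]
    Path(path).write_text(
        json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8"
    )


def read_annotated_json(path: str | Path) -> list[AnnotatedEntry]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        AnnotatedEntry(
            d["entry_id"],
            d["text"],
            [TaggedSpan(*s) for s in d["spans"]],
            d.get("phylum"),
        )
        for d in payload
    ]
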