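"""Seeded synthetic corpora of classical-style formula entries.

Real formulary e-books cannot be bundled, so every downstream stage is
exercised on generated corpora that reproduce the structural shapes of
classical entries:

1. an herb list with parenthesized preparation/dosage notes
   (赤茯苓(去黑皮三兩) 葶藶(紙上炒半兩) …);
2. a symptom line 治…宜服…方 followed by the herb list;
3. a formula name ending in 湯 on its own line, then a 治… indication
   block, then the herb list;
4. a one-line 治…方 用… entry with the herbs inline.

Herb membership per entry is drawn by a two-stage Bernoulli sampler so
that each *planted* herb pair attains a target support and confidence:
the antecedent appears with probability support/confidence and the
consequent with probability confidence given the antecedent; remaining
lexicon herbs are independent background at ``background_herb_rate``.
Planted herbs are excluded from the background pool so the targets are
exact in expectation.

Alongside the text the generator emits a :class:`GroundTruth`: per-entry
character spans (0-based, half-open) for every rendered term, and the
per-entry transaction (herb/adjunct itemset), which is what a perfect
tagger must recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .extraction import TaggedSpan, Transaction, write_transactions_tsv
from .lexicon import Lexicon, LexiconEntry

__all__ = [
    "PlantedRule",
    "SynthSpec",
    "GroundTruth",
    "default_lexicon",
    "default_spec",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
]

_HERBS = (
    "甘草 當歸 人參 黄芩 大黄 枳殻 白朮 茯苓 防風 澤瀉 "
    "乾薑 升麻 牛膝 知母 附子 木香 芍藥 半夏 桔梗 陳皮"
).split()
_ADJUNCTS = ["蜜", "醋"]
_FORMULAS = ["茯苓補心湯", "半夏補心湯", "石膏丸", "牛黃散", "補心湯"]

_PREPARATIONS = [
    "炮", "炙銼", "去粗皮", "半兩", "一兩", "各三分", "酒浸切焙",
    "去黑皮三兩", "紙上炒半兩",
]
_SYMPTOMS = [
    "頭痛不止。心神煩悶", "心氣不足。善悲愁恚怒", "筋脈攣急。言語謇澀",
    "咽喉痛。五心熱", "神思昏憒", "面黃煩悶", "心中脹滿悲憂",
]
_NOISE_CHARS = list("之而者也矣焉於其")
_PHYLA = ["心臟門", "肝臟門", "肺臟門", "脾臟門", "腎臟門"]


def default_lexicon() -> Lexicon:
    """The full synthetic lexicon: herbs, adjuncts, and formula names."""
    entries = [LexiconEntry(t, "herb") for t in _HERBS]
    entries += [LexiconEntry(t, "adjunct") for t in _ADJUNCTS]
    entries += [LexiconEntry(t, "formula") for t in _FORMULAS]
    return Lexicon(entries)


@dataclass(frozen=True)
class PlantedRule:
    """A dependent herb pair with target support and confidence."""

    antecedent: str
    consequent: str
    support: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0 < self.support <= 1 or not 0 < self.confidence <= 1:
            raise ValueError("support and confidence must lie in (0, 1]")
        if self.support > self.confidence:
            raise ValueError(
                "target support must not exceed target confidence "
                "(antecedent marginal = support/confidence would exceed 1)"
            )


@dataclass
class SynthSpec:
    """Full description of one synthetic corpus; seed fixed => bytes fixed."""

    n_entries: int
    lexicon: Lexicon = field(default_factory=default_lexicon)
    planted_rules: list[PlantedRule] = field(default_factory=list)
    background_herb_rate: float = 0.3
    noise_token_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entries < 1:
            raise ValueError("n_entries must be positive")
        for rate in (self.background_herb_rate, self.noise_token_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        planted_terms = set()
        for r in self.planted_rules:
            for t in (r.antecedent, r.consequent):
                if t not in self.lexicon:
                    raise ValueError(
                        f"planted rule references term {t!r} absent from lexicon"
                    )
            pair = {r.antecedent, r.consequent}
            if planted_terms & pair:
                raise ValueError(
                    "planted rules must use disjoint herb pairs; "
                    "shared herbs couple the samplers and shift the targets"
                )
            planted_terms |= pair


def default_spec(n_entries: int = 2000, seed: int = 0) -> SynthSpec:
    """Study conditions: planted pairs at the support/confidence levels of
    the headline mined pairs (honey–licorice 0.93/0.99, angelica-type pair
    0.91/0.98, rhubarb–skullcap 0.801/0.94)."""
    return SynthSpec(
        n_entries=n_entries,
        planted_rules=[
            PlantedRule("蜜", "甘草", 0.93, 0.99),
            PlantedRule("當歸", "枳殻", 0.91, 0.98),
            PlantedRule("大黄", "黄芩", 0.801, 0.94),
        ],
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Per-entry annotation the tagger must reproduce."""

    spans: list[list[TaggedSpan]]
    transactions: list[Transaction]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spans": [
                [[s.start, s.end, s.term, s.category] for s in entry]
                for entry in self.spans
            ],
            "transactions": [
                {
                    "entry_id": t.entry_id,
                    "items": list(t.ordered_items),
                    "phylum": t.phylum,
                    "formula": t.formula,
                }
                for t in self.transactions
            ],
        }
        Path(path).write_text(
            json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        spans = [
            [TaggedSpan(*s) for s in entry] for entry in payload["spans"]
        ]
        transactions = [
            Transaction(
                d["entry_id"], frozenset(d["items"]), tuple(d["items"]),
                d.get("phylum"), d.get("formula"),
            )
            for d in payload["transactions"]
        ]
        return cls(spans, transactions)

    def write_transactions_tsv(self, path: str | Path) -> None:
        write_transactions_tsv(self.transactions, path)


def _sample_items(spec: SynthSpec, rng: np.random.Generator) -> list[str]:
    planted = {t for r in spec.planted_rules for t in (r.antecedent, r.consequent)}
    items: list[str] = []
    for r in spec.planted_rules:
        if rng.random() < r.support / r.confidence:
            items.append(r.antecedent)
            if rng.random() < r.confidence:
                items.append(r.consequent)
    background = [
        t for t in spec.lexicon.terms_of("herb", "adjunct") if t not in planted
    ]
    items += [t for t in background if rng.random() < spec.background_herb_rate]
    if not items:
        items.append(background[int(rng.integers(len(background)))])
    order = rng.permutation(len(items))
    return [items[i] for i in order]


def _render_herb_tokens(
    items: Sequence[str],
    spec: SynthSpec,
    rng: np.random.Generator,
    offset: int,
    spans: list[TaggedSpan],
) -> tuple[str, int]:
    """Render the herb list, recording a span per item. Returns (text, offset)."""
    parts: list[str] = []
    for term in items:
        if rng.random() < spec.noise_token_rate:
            noise = "".join(
                rng.choice(_NOISE_CHARS, size=int(rng.integers(1, 3)))
            )
            parts.append(noise)
            offset += len(noise) + 1
        spans.append(
            TaggedSpan(offset, offset + len(term), term, spec.lexicon.category(term))
        )
        token = term
        if rng.random() < 0.6:
            prep = _PREPARATIONS[int(rng.integers(len(_PREPARATIONS)))]
            token += f"({prep})"
        parts.append(token)
        offset += len(token) + 1
    return " ".join(parts), offset - 1


def _render_entry(
    items: Sequence[str], spec: SynthSpec, rng: np.random.Generator
) -> tuple[str, list[TaggedSpan], str | None]:
    shape = int(rng.choice(4, p=[0.4, 0.2, 0.2, 0.2]))
    symptom = _SYMPTOMS[int(rng.integers(len(_SYMPTOMS)))]
    spans: list[TaggedSpan] = []
    formula_name: str | None = None
    if shape == 0:  # herb list only
        text, _ = _render_herb_tokens(items, spec, rng, 0, spans)
    elif shape == 1:  # 治…宜服X方 line + herb list
        formula_name = _FORMULAS[int(rng.integers(len(_FORMULAS)))]
        head = f"治{symptom}。宜服"
        spans.append(
            TaggedSpan(len(head), len(head) + len(formula_name), formula_name,
                       "formula")
        )
        line1 = f"{head}{formula_name}方"
        body, _ = _render_herb_tokens(items, spec, rng, len(line1) + 1, spans)
        text = f"{line1}\n{body}"
    elif shape == 2:  # name 湯/丸 line, 治… line, herb list
        formula_name = _FORMULAS[int(rng.integers(len(_FORMULAS)))]
        spans.append(TaggedSpan(0, len(formula_name), formula_name, "formula"))
        line2 = f"治{symptom}"
        start = len(formula_name) + 1 + len(line2) + 1
        body, _ = _render_herb_tokens(items, spec, rng, start, spans)
        text = f"{formula_name}\n{line2}\n{body}"
    else:  # 治…方 用… one line
        head = f"治{symptom}方 用"
        body, _ = _render_herb_tokens(items, spec, rng, len(head), spans)
        text = head + body
    return text, spans, formula_name


def generate_corpus(spec: SynthSpec) -> tuple[list[str], GroundTruth]:
    """Generate entry texts and their ground truth, deterministically."""
    if len(spec.lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    rng = np.random.default_rng(spec.seed)
    texts: list[str] = []
    all_spans: list[list[TaggedSpan]] = []
    transactions: list[Transaction] = []
    for i in range(spec.n_entries):
        entry_id = f"E{i:05d}"
        phylum = _PHYLA[int(rng.integers(len(_PHYLA)))]
        items = _sample_items(spec, rng)
        text, spans, formula_name = _render_entry(items, spec, rng)
        texts.append(text)
        all_spans.append(spans)
        transactions.append(
            Transaction(entry_id, frozenset(items), tuple(items), phylum,
                        formula_name)
        )
    return texts, GroundTruth(all_spans, transactions)


def write_corpus(texts: Sequence[str], path: str | Path) -> None:
    """One entry per blank-line-separated paragraph, UTF-8."""
    Path(path).write_text("\n\n".join(texts) + "\n", encoding="utf-8")


def read_corpus(path: str | Path) -> list[tuple[str, str]]:
    """Read a corpus file back as ``(entry_id, text)`` pairs."""
    raw = Path(path).read_text(encoding="utf-8")
    paragraphs = [p.strip("\n") for p in raw.split("\n\n") if p.strip()]
    return [(f"E{i:05d}", p) for i, p in enumerate(paragraphs)]
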