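"""From-scratch Apriori mining and association-rule metrics.

Transactions are herb itemsets, one per formula entry.  The miner is the
classic level-wise algorithm: frequent 1-itemsets first, then candidate
k-itemsets joined from (k-1)-itemsets sharing a prefix, pruned by the
anti-monotone property (every subset of a frequent itemset is frequent),
counted exactly via transaction-id set intersection — no sampling.

Rules X -> Y are emitted for every frequent itemset Z and every nonempty
proper subset X (Y = Z \\ X), with the five standard metrics::

    support    = P(X ∪ Y)
    confidence = P(X ∪ Y) / P(X)
    lift       = P(X ∪ Y) / (P(X) · P(Y))
    leverage   = P(X ∪ Y) − P(X) · P(Y)
    conviction = (1 − P(Y)) / (1 − confidence)   (+inf when confidence = 1)

lift > 1 indicates a positive association between antecedent and
consequent; lift is symmetric in X and Y for pair rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FrequentItemset",
    "AssociationRule",
    "apriori",
    "generate_rules",
    "rank_rules",
    "rules_to_dataframe",
    "write_rules_tsv",
]

RULE_COLUMNS = [
    "antecedents", "consequents", "antecedent support", "consequent support",
    "support", "confidence", "lift", "leverage", "conviction",
]


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    support: float
    count: int


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]
    antecedent_support: float
    consequent_support: float
    support: float
    confidence: float
    lift: float
    leverage: float
    conviction: float

    def _key(self) -> tuple:
        return (tuple(sorted(self.antecedent)), tuple(sorted(self.consequent)))


def _normalize(transactions: Iterable[Iterable[str]]) -> list[frozenset[str]]:
    return [frozenset(t) for t in transactions]


def apriori(
    transactions: Sequence[Iterable[str]], min_support: float
) -> list[FrequentItemset]:
    """All itemsets with support >= *min_support*, by level-wise search."""
    if not 0 < min_support <= 1:
        raise ValueError("min_support must lie in (0, 1]")
    tsets = _normalize(transactions)
    n = len(tsets)
    if n == 0:
        raise ValueError("transaction list is empty")

    tids: dict[frozenset[str], set[int]] = {}
    for idx, t in enumerate(tsets):
        for item in t:
            tids.setdefault(frozenset([item]), set()).add(idx)

    def frequent(count: int) -> bool:
        return count / n >= min_support

    out: list[FrequentItemset] = []
    level = {
        iset: ids for iset, ids in tids.items() if frequent(len(ids))
    }
    while level:
        out.extend(
            FrequentItemset(iset, len(ids) / n, len(ids))
            for iset, ids in level.items()
        )
        keys = sorted(level, key=lambda s: tuple(sorted(s)))
        frequent_prev = set(level)
        nxt: dict[frozenset[str], set[int]] = {}
        for a, b in combinations(keys, 2):
            cand = a | b
            if len(cand) != len(a) + 1 or cand in nxt:
                continue
            # anti-monotone pruning: all (k-1)-subsets must be frequent
            if any(
                cand - frozenset([item]) not in frequent_prev for item in cand
            ):
                continue
            ids = level[a] & level[b]
            if frequent(len(ids)):
                nxt[cand] = ids
        level = nxt
    out.sort(key=lambda f: (len(f.items), -f.support, tuple(sorted(f.items))))
    return out


def generate_rules(
    itemsets: Sequence[FrequentItemset], min_confidence: float | None = None
) -> list[AssociationRule]:
    """Emit X -> Z\\X for every frequent Z and nonempty proper subset X.

    No confidence cut-off is applied by default; the mined tables are
    rankings, not filtered lists.
    """
    support = {f.items: f.support for f in itemsets}
    rules: list[AssociationRule] = []
    for f in itemsets:
        if len(f.items) < 2:
            continue
        items = sorted(f.items)
        for r in range(1, len(items)):
            for ante in combinations(items, r):
                x = frozenset(ante)
                y = f.items - x
                sx, sy = support[x], support[y]
                conf = f.support / sx
                conviction = (
                    math.inf if conf >= 1 else (1 - sy) / (1 - conf)
                )
                rule = AssociationRule(
                    x, y, sx, sy, f.support, conf,
                    f.support / (sx * sy), f.support - sx * sy, conviction,
                )
                if min_confidence is None or conf >= min_confidence:
                    rules.append(rule)
    rules.sort(key=lambda r: r._key())
    return rules


_RANK_KEYS = ("support", "confidence", "lift", "leverage", "conviction")


def rank_rules(
    rules: Sequence[AssociationRule], key: str = "support", descending: bool = True
) -> list[AssociationRule]:
    """Stable sort by a metric; ties break lexicographically by itemsets."""
    if key not in _RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; expected one of {_RANK_KEYS}")
    return sorted(
        rules,
        key=lambda r: (
            -getattr(r, key) if descending else getattr(r, key),
            r._key(),
        ),
    )


def rules_to_dataframe(
    rules: Sequence[AssociationRule], ndigits: int | None = 3
) -> pd.DataFrame:
    """Tabular view in the standard column order; metrics rounded for display."""
    rnd = (lambda v: v) if ndigits is None else (lambda v: round(v, ndigits))
    rows = [
        {
            "antecedents": str(sorted(r.antecedent)),
            "consequents": str(sorted(r.consequent)),
            "antecedent support": rnd(r.antecedent_support),
            "consequent support": rnd(r.consequent_support),
            "support": rnd(r.support),
            "confidence": rnd(r.confidence),
            "lift": rnd(r.lift),
            "leverage": rnd(r.leverage),
            "conviction": rnd(r.conviction) if math.isfinite(r.conviction) else math.inf,
        }
        for r in rules
    ]
    return pd.DataFrame(rows, columns=RULE_COLUMNS)


def write_rules_tsv(
    rules: Sequence[AssociationRule], path: str | Path, ndigits: int | None = 3
) -> None:
    rules_to_dataframe(rules, ndigits).to_csv(path, sep="\t", index=False)
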