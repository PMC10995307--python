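"""Co-occurrence network of herbs and formulas.

Herb–herb edges connect terms that appear in the same formula entry,
weighted by the number of entries containing both; when a transaction
carries a formula name, bipartite formula–herb edges link the formula
node to its member herbs.  The graph is undirected with no self-loops.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .extraction import Transaction

__all__ = [
    "build_network",
    "sample_pairs",
    "write_edgelist_tsv",
    "read_edgelist_tsv",
    "write_graphml",
]


def build_network(
    transactions: Sequence[Transaction],
    min_weight: int = 1,
    include_formula_links: bool = True,
) -> nx.Graph:
    """Build the co-occurrence graph; edges below *min_weight* are dropped.

    Node attribute ``category`` is ``herb`` (any itemset member, adjuncts
    included) or ``formula``; edge attribute ``weight`` is the exact
    co-occurrence count over the transactions.
    """
    if not transactions:
        raise ValueError("need at least one transaction")
    g = nx.Graph()
    weights: dict[tuple[str, str], int] = {}
    for t in transactions:
        for a, b in combinations(sorted(t.items), 2):
            weights[(a, b)] = weights.get((a, b), 0) + 1
        if include_formula_links and t.formula:
            for h in t.items:
                key = tuple(sorted((t.formula, h)))
                weights[key] = weights.get(key, 0) + 1
    # insertion in sorted order keeps node/edge iteration independent of
    # per-process hash randomization
    for t in transactions:
        for item in sorted(t.items):
            g.add_node(item, category="herb")
        if include_formula_links and t.formula:
            g.add_node(t.formula, category="formula")
    for (a, b), w in sorted(weights.items()):
        if w >= min_weight and a != b:
            g.add_edge(a, b, weight=w)
    return g


def sample_pairs(
    network: nx.Graph, k: int = 200, seed: int | None = None
) -> list[tuple[str, str]]:
    """Uniform sample of *k* distinct edges (herb pairs) without replacement."""
    pairs = sorted(tuple(sorted(e)) for e in network.edges)
    if k >= len(pairs):
        if k > len(pairs):
            warnings.warn(
                f"requested {k} pairs but only {len(pairs)} available; "
                "returning all"
            )
        return pairs
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=k, replace=False)
    return [pairs[i] for i in sorted(idx)]


def write_edgelist_tsv(network: nx.Graph, path: str | Path) -> None:
    """``node_a TAB node_b TAB weight``, sorted, UTF-8."""
    lines = [
        f"{a}\t{b}\t{d['weight']}"
        for a, b, d in sorted(
            (tuple(sorted((u, v))) + (d,) for u, v, d in network.edges(data=True))
        )
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_edgelist_tsv(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        a, b, w = line.split("\t")
        g.add_edge(a, b, weight=int(w))
    return g


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, path, encoding="utf-8")
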