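"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: power-set enumeration for frequent
itemsets and rule metrics, and composition-enumeration for exact tests
on contingency tables.  They share no code with the package paths they
check.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
from scipy.special import gammaln


def brute_force_frequent_itemsets(transactions, min_support):
    """Enumerate every nonempty itemset over the observed alphabet."""
    tsets = [frozenset(t) for t in transactions]
    n = len(tsets)
    alphabet = sorted(set().union(*tsets)) if tsets else []
    out = {}
    for k in range(1, len(alphabet) + 1):
        for combo in combinations(alphabet, k):
            s = frozenset(combo)
            count = sum(1 for t in tsets if s <= t)
            if count / n >= min_support:
                out[s] = count
    return out


def brute_force_rule_metrics(transactions, antecedent, consequent):
    """(support_x, support_y, support, confidence, lift, leverage, conviction)
    computed by direct counting."""
    tsets = [frozenset(t) for t in transactions]
    n = len(tsets)
    x, y = frozenset(antecedent), frozenset(consequent)
    sx = sum(1 for t in tsets if x <= t) / n
    sy = sum(1 for t in tsets if y <= t) / n
    sxy = sum(1 for t in tsets if (x | y) <= t) / n
    conf = sxy / sx
    conviction = math.inf if conf >= 1 else (1 - sy) / (1 - conf)
    return sx, sy, sxy, conf, sxy / (sx * sy), sxy - sx * sy, conviction


def _compositions(total, parts):
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _compositions(total - head, parts - 1):
            yield (head,) + tail


def fisher_exact_oracle(counts):
    """Two-sided exact p by enumerating every margin-preserving table."""
    counts = np.asarray(counts, dtype=np.int64)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    lg_margins = gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
    lg_n = gammaln(n + 1)

    def logprob(m):
        return float(lg_margins - lg_n - gammaln(np.asarray(m) + 1).sum())

    logp_obs = logprob(counts)
    total = 0.0
    row_options = [list(_compositions(int(r), counts.shape[1])) for r in rows]
    for combo in product(*row_options):
        m = np.array(combo)
        if (m.sum(axis=0) == cols).all():
            lp = logprob(m)
            if lp <= logp_obs + 1e-7:
                total += math.exp(lp)
    return min(total, 1.0)
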