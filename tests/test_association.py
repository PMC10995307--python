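import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herbmine.association import (
    apriori, generate_rules, rank_rules, rules_to_dataframe,
)
from herbmine.reference import rule_metric_rows, spotlight_rule_rows, SPOTLIGHT

from oracles import brute_force_frequent_itemsets, brute_force_rule_metrics

ITEMS = list("abcdefghij")


def random_transactions(rng, n_items=None, n_tx=None):
    n_items = n_items or int(rng.integers(2, 11))
    n_tx = n_tx or int(rng.integers(1, 65))
    alphabet = ITEMS[:n_items]
    txs = []
    for _ in range(n_tx):
        mask = rng.random(n_items) < rng.uniform(0.2, 0.8)
        txs.append({a for a, m in zip(alphabet, mask) if m} or {alphabet[0]})
    return txs


class TestApriori:
    def test_hand_enumerated_example(self):
        got = {
            f.items: (f.support, f.count)
            for f in apriori([{"a", "b"}, {"a", "b"}, {"a"}, {"b"}], 0.5)
        }
        assert got == {
            frozenset("a"): (0.75, 3),
            frozenset("b"): (0.75, 3),
            frozenset("ab"): (0.5, 2),
        }

    def test_min_support_one_keeps_only_universal_itemsets(self):
        got = apriori([{"a", "b"}, {"a"}], 1.0)
        assert {f.items for f in got} == {frozenset("a")}

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            apriori([], 0.5)
        with pytest.raises(ValueError):
            apriori([{"a"}], 0.0)
        with pytest.raises(ValueError):
            apriori([{"a"}], 1.5)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_power_set_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        txs = random_transactions(rng)
        min_support = float(rng.uniform(0.1, 0.9))
        expected = brute_force_frequent_itemsets(txs, min_support)
        got = {f.items: f.count for f in apriori(txs, min_support)}
        assert got == expected

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.sets(st.sampled_from("abcde"), min_size=1, max_size=5),
            min_size=1, max_size=30,
        ),
        st.floats(min_value=0.05, max_value=1.0),
    )
    def test_anti_monotonicity_over_emitted_set(self, txs, min_support):
        emitted = {f.items for f in apriori(txs, min_support)}
        for iset in emitted:
            for item in iset:
                if len(iset) > 1:
                    assert iset - {item} in emitted


class TestRules:
    def test_metrics_against_direct_counting(self):
        rng = np.random.default_rng(42)
        txs = random_transactions(rng, n_items=6, n_tx=40)
        rules = generate_rules(apriori(txs, 0.2))
        assert rules
        for r in rules:
            sx, sy, sxy, conf, lift, lev, conv = brute_force_rule_metrics(
                txs, r.antecedent, r.consequent
            )
            assert r.antecedent_support == pytest.approx(sx)
            assert r.support == pytest.approx(sxy)
            assert r.confidence == pytest.approx(conf)
            assert r.lift == pytest.approx(lift)
            assert r.leverage == pytest.approx(lev)
            assert r.conviction == conv or r.conviction == pytest.approx(conv)

    def test_lift_symmetric_for_pair_rules(self):
        rng = np.random.default_rng(1)
        txs = random_transactions(rng, n_items=5, n_tx=30)
        rules = generate_rules(apriori(txs, 0.2))
        lifts = {(tuple(sorted(r.antecedent)), tuple(sorted(r.consequent))): r.lift
                 for r in rules}
        for (a, c), lift in lifts.items():
            assert lifts[(c, a)] == pytest.approx(lift)

    def test_independent_items_have_unit_lift_zero_leverage(self):
        # a and b occur independently: P(ab) = P(a)P(b) = 0.25 exactly
        txs = [{"a", "b"}, {"a"}, {"b"}, set("x")]
        rules = generate_rules(apriori(txs, 0.2))
        rule = next(r for r in rules
                    if r.antecedent == {"a"} and r.consequent == {"b"})
        assert rule.lift == pytest.approx(1.0)
        assert rule.leverage == pytest.approx(0.0)

    def test_conviction_infinite_at_full_confidence(self):
        rules = generate_rules(apriori([{"a", "b"}, {"a", "b"}], 0.5))
        rule = next(r for r in rules if r.antecedent == {"a"})
        assert rule.confidence == 1.0
        assert math.isinf(rule.conviction)

    def test_antecedent_disjoint_from_consequent_and_support_bound(self):
        rng = np.random.default_rng(3)
        txs = random_transactions(rng)
        for r in generate_rules(apriori(txs, 0.3)):
            assert not (r.antecedent & r.consequent)
            assert r.support <= min(r.antecedent_support, r.consequent_support) + 1e-12


class TestRanking:
    def rules(self):
        rng = np.random.default_rng(5)
        return generate_rules(apriori(random_transactions(rng, 6, 50), 0.2))

    def test_sort_is_a_permutation(self):
        rules = self.rules()
        ranked = rank_rules(rules, key="support")
        assert sorted(map(id, ranked)) == sorted(map(id, rules))

    @pytest.mark.parametrize("key", ["support", "lift"])
    def test_descending_order_with_lexicographic_ties(self, key):
        ranked = rank_rules(self.rules(), key=key)
        for a, b in zip(ranked, ranked[1:]):
            va, vb = getattr(a, key), getattr(b, key)
            assert va > vb or (va == vb and a._key() <= b._key())

    def test_reversing_direction_reverses_extremes(self):
        rules = self.rules()
        asc = rank_rules(rules, key="lift", descending=False)
        desc = rank_rules(rules, key="lift", descending=True)
        assert asc[0].lift == desc[-1].lift

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown ranking key"):
            rank_rules(self.rules(), key="entropy")


class TestPublishedMetricRows:
    """Recompute confidence and lift from each published row's supports."""

    def test_spotlight_rows_reproduce_at_three_decimals(self):
        df = spotlight_rule_rows()
        assert len(df) == len(SPOTLIGHT)
        for row in df.itertuples():
            conf = row.support / row.antecedent_support
            lift = row.support / (row.antecedent_support * row.consequent_support)
            metric = dict(
                (m[:2], m[2]) for m in SPOTLIGHT
            )[(row.antecedents, row.consequents)]
            if metric == "confidence":
                assert round(conf, 3) == row.confidence
            else:
                assert round(lift, 3) == row.lift

    def test_all_rows_consistent_within_rounding_propagation(self):
        # supports are printed at 3 decimals, so recomputed metrics can shift
        # by up to ~0.002 against the printed (unrounded-input) columns
        for row in rule_metric_rows().itertuples():
            conf = row.support / row.antecedent_support
            lift = row.support / (row.antecedent_support * row.consequent_support)
            lev = row.support - row.antecedent_support * row.consequent_support
            assert conf == pytest.approx(row.confidence, abs=2e-3)
            assert lift == pytest.approx(row.lift, abs=2e-3)
            assert lev == pytest.approx(row.leverage, abs=2e-3)


def test_dataframe_mirrors_standard_column_order():
    df = rules_to_dataframe(generate_rules(apriori([{"a", "b"}], 1.0)))
    assert list(df.columns) == [
        "antecedents", "consequents", "antecedent support", "consequent support",
        "support", "confidence", "lift", "leverage", "conviction",
    ]
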