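"""Rough-set core: reducts, rule induction, significance, voting, CV."""

import itertools
from math import comb

import numpy as np
import pytest

from copredict.rules import (DecisionTable, Descriptor, Rule, RuleModel,
                             classify, classify_table, compute_reducts,
                             cross_validate, induce_rules, rule_pvalue,
                             rule_pvalue_counts, train_model)
from tests.conftest import random_table


# ------------------------------------------------------------- oracles

def brute_force_reducts(table: DecisionTable) -> list[tuple[str, ...]]:
    """Enumerate all attribute subsets; keep those preserving pairwise
    discernibility for every cross-class pair that is discernible at all,
    then filter to minimal sets."""
    n = table.n_objects
    feats = range(len(table.features))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if table.y[i] != table.y[j]
             and (table.X[i] != table.X[j]).any()]

    def discerns(subset, i, j):
        return any(table.X[i, f] != table.X[j, f] for f in subset)

    covering = [s for size in range(0, len(table.features) + 1)
                for s in itertools.combinations(feats, size)
                if all(discerns(s, i, j) for i, j in pairs)]
    minimal = [s for s in covering
               if not any(set(t) < set(s) for t in covering)]
    return sorted(tuple(table.features[f] for f in s) for s in minimal)


def brute_force_matches(table: DecisionTable, lhs) -> set[str]:
    out = set()
    for i, obj in enumerate(table.objects):
        codes = dict(zip(table.features, table.X[i]))
        if all(codes[d.gene] == d.level for d in lhs):
            out.add(obj)
    return out


# ------------------------------------------------------------- reducts

class TestReducts:
    def test_hand_worked_example_unique_minimal_reduct(self, toy_table):
        # cross-class discernibility: every pair differs on g1; two pairs
        # also differ on g2, so {g1} is the unique minimal hitting set
        assert compute_reducts(toy_table, "exhaustive") == [("g1",)]

    def test_johnson_outputs_contain_a_minimal_reduct(self, toy_table):
        for red in compute_reducts(toy_table, "johnson", n_reducts=5, seed=1):
            assert set(red) >= {"g1"} or red == ("g1",)

    def test_constant_decision_gives_empty_reduct_and_no_rules(self):
        t = DecisionTable(["a", "b"], ["g1"], np.array([[1], [2]]),
                          np.array(["DA1", "DA1"], dtype=object))
        reds = compute_reducts(t, "exhaustive")
        assert reds == [()]
        assert induce_rules(t, reds) == []

    def test_exhaustive_refused_above_feature_limit(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, 4, 25)
        with pytest.raises(ValueError, match="refused"):
            compute_reducts(t, "exhaustive")

    def test_unknown_method_rejected(self, toy_table):
        with pytest.raises(ValueError):
            compute_reducts(toy_table, "nope")

    def test_exhaustive_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            t = random_table(rng, int(rng.integers(3, 8)),
                             int(rng.integers(2, 6)))
            assert sorted(compute_reducts(t, "exhaustive")) == \
                brute_force_reducts(t)

    def test_johnson_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        t = random_table(rng, 10, 6)
        a = compute_reducts(t, "johnson", n_reducts=5, seed=3)
        b = compute_reducts(t, "johnson", n_reducts=5, seed=3)
        assert a == b


# ------------------------------------------------------------- rules

class TestInduceRules:
    def test_worked_example_two_rules(self, toy_table):
        rules = induce_rules(toy_table, [("g1",)])
        assert len(rules) == 2
        by_dec = {r.decision: r for r in rules}
        r3 = by_dec["DA3"]
        assert r3.lhs == (Descriptor("g1", 3),)
        assert r3.support == 2 and r3.accuracy == 1.0
        assert r3.support_set == frozenset({"o1", "o3"})
        r1 = by_dec["DA1"]
        assert r1.support == 2 and r1.accuracy == 1.0

    def test_identical_reduct_values_merge(self, toy_table):
        # o1 and o3 share g1=3: one rule with support 2, not two rules
        rules = induce_rules(toy_table, [("g1",)])
        assert sum(r.lhs == (Descriptor("g1", 3),) for r in rules) == 1

    def test_inconsistent_lhs_majority_decision(self):
        t = DecisionTable(["a", "b", "c"], ["g"], np.array([[2], [2], [2]]),
                          np.array(["DA3", "DA3", "DA1"], dtype=object))
        rules = induce_rules(t, [("g",)])
        assert len(rules) == 1
        assert rules[0].decision == "DA3"
        assert rules[0].accuracy == pytest.approx(2 / 3)

    def test_support_sets_match_brute_force_on_random_tables(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            t = random_table(rng, 12, 5)
            reds = compute_reducts(t, "johnson", n_reducts=4, seed=0)
            for r in induce_rules(t, reds):
                assert r.support_set == brute_force_matches(t, r.lhs)
                assert r.support == len(r.support_set)


class TestRulePValue:
    def test_hypergeometric_example(self):
        # N=10, K=5, n=3, k=3 -> C(5,3)/C(10,3) = 10/120
        assert rule_pvalue_counts(10, 5, 3, 3) == pytest.approx(10 / 120,
                                                                abs=1e-12)

    def test_matches_subset_enumeration(self):
        # enumerate all C(10,3) draws of 3 objects from 10 (5 in class)
        N, K, n = 10, 5, 3
        objs = [1] * K + [0] * (N - K)
        for k0 in range(n + 1):
            count = sum(1 for pick in itertools.combinations(objs, n)
                        if sum(pick) >= k0)
            assert rule_pvalue_counts(N, K, n, k0) == pytest.approx(
                count / comb(N, n), abs=1e-10)

    def test_zero_matches_and_single_class(self):
        assert rule_pvalue_counts(10, 5, 0, 0) == 1.0
        assert rule_pvalue_counts(10, 5, 3, 0) == 1.0  # X>=0 is certain
        assert rule_pvalue_counts(8, 8, 3, 3) == pytest.approx(1.0)

    def test_rule_pvalue_recomputes_from_table(self, toy_table):
        rules = induce_rules(toy_table, [("g1",)])
        for r in rules:
            assert rule_pvalue(r, toy_table) == pytest.approx(r.p_value,
                                                              abs=1e-12)


class TestClassify:
    def model(self, toy_table):
        return train_model(toy_table, method="exhaustive")

    def test_matching_rule_wins(self, toy_table):
        model = self.model(toy_table)
        assert classify({"g1": 3}, model) == "DA3"
        assert classify({"g1": 1}, model) == "DA1"

    def test_no_match_falls_back_to_majority(self, toy_table):
        model = RuleModel(rules=[Rule((Descriptor("g1", 3),), "DA3",
                                      frozenset({"o1"}), 1, 1.0, 0.5, 0.5)],
                          majority_class="DA3")
        assert classify({"g1": 2}, model) == "DA3"
        assert classify({"g1": 2}, model, fallback="abstain") == "<abstain>"

    def test_tie_abstains_when_requested(self):
        rules = [
            Rule((Descriptor("g1", 2),), "DA3", frozenset({"a"}), 1, 1.0, 1.0, 0.5),
            Rule((Descriptor("g2", 2),), "DA1", frozenset({"b"}), 1, 1.0, 1.0, 0.5),
        ]
        model = RuleModel(rules=rules, majority_class="DA1")
        assert classify({"g1": 2, "g2": 2}, model, fallback="abstain") == "<abstain>"

    def test_unknown_gene_rejected(self, toy_table):
        with pytest.raises(KeyError):
            classify({"other": 1}, self.model(toy_table))

    def test_invariant_to_rule_order(self):
        rng = np.random.default_rng(31)
        t = random_table(rng, 20, 5)
        model = train_model(t, n_reducts=5, seed=2)
        base = classify_table(t, model)
        for _ in range(3):
            rules = list(model.rules)
            rng.shuffle(rules)
            shuffled = RuleModel(rules=rules,
                                 majority_class=model.majority_class)
            assert classify_table(t, shuffled) == base


class TestCrossValidate:
    def test_leave_one_out_on_small_fixture(self):
        rng = np.random.default_rng(41)
        X = np.array([[3]] * 6 + [[1]] * 6)
        t = DecisionTable([f"o{i}" for i in range(12)], ["g"], X,
                          np.array(["DA3"] * 6 + ["DA1"] * 6, dtype=object))
        res = cross_validate(t, folds=6, seed=0)
        assert 0.0 <= res.accuracy <= 1.0
        assert len(res.fold_accuracies) == 6
        assert res.accuracy == 1.0  # perfectly separable

    def test_class_smaller_than_folds_rejected(self):
        t = DecisionTable(["a", "b", "c"], ["g"], np.array([[1], [2], [3]]),
                          np.array(["DA1", "DA1", "DA3"], dtype=object))
        with pytest.raises(ValueError, match="fewer folds"):
            cross_validate(t, folds=2)
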