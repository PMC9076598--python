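"""Support-matrix clustering, rule-cluster association, statistics."""

import numpy as np
import pandas as pd
import pytest

from copredict.rules import DecisionTable, Descriptor, Rule
from copredict.subgroups import (ClusterAssignment,
                                 associate_rules_to_clusters, binary_distance,
                                 cluster_phenotype_tests, hcluster,
                                 permutation_validate, rule_phenotype_tests,
                                 support_matrix)


def make_rule(support_set, decision="DA3", gene="g", level=3):
    return Rule((Descriptor(gene, level),), decision, frozenset(support_set),
                len(support_set), 1.0, 0.5, 0.01)


class TestSupportMatrix:
    def test_membership_column(self):
        r = make_rule({"o1", "o2"})
        M = support_matrix([r], ["o1", "o2", "o3"])
        assert M["R001"].tolist() == [1, 1, 0]

    def test_zero_row_flagged(self, caplog):
        import logging
        r = make_rule({"o1"})
        with caplog.at_level(logging.WARNING, logger="copredict.subgroups"):
            support_matrix([r], ["o1", "o2"])
        assert "support no rule" in caplog.text

    def test_matches_brute_force_rematching(self):
        rng = np.random.default_rng(0)
        objects = [f"o{i}" for i in range(15)]
        rules = [make_rule(set(rng.choice(objects, size=rng.integers(1, 8),
                                          replace=False)), gene=f"g{i}")
                 for i in range(6)]
        M = support_matrix(rules, objects)
        for j, r in enumerate(rules):
            for o in objects:
                assert M.loc[o, f"R{j+1:03d}"] == int(o in r.support_set)


class TestBinaryDistance:
    def test_worked_example(self):
        M = pd.DataFrame([[1, 1, 0, 0], [1, 0, 1, 0]], index=["x", "y"])
        d = binary_distance(M)
        assert d.loc["x", "y"] == pytest.approx(2 / 3)

    def test_identical_rows_zero(self):
        M = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["x", "y"])
        assert binary_distance(M).loc["x", "y"] == 0.0

    def test_no_active_column_convention_zero(self):
        M = pd.DataFrame([[0, 0], [0, 0]], index=["x", "y"])
        assert binary_distance(M).loc["x", "y"] == 0.0

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        M = pd.DataFrame(rng.integers(0, 2, size=(20, 30)))
        D = binary_distance(M)
        A = M.to_numpy()
        for i in range(20):
            for j in range(20):
                both = int(((A[i] == 1) & (A[j] == 1)).sum())
                only = int((A[i] != A[j]).sum())
                expect = only / (both + only) if both + only else 0.0
                assert D.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_pseudo_metric_properties(self):
        rng = np.random.default_rng(2)
        M = pd.DataFrame(rng.integers(0, 2, size=(12, 8)))
        D = binary_distance(M).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        n = len(D)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-12


class TestHCluster:
    def test_identical_blocks_recovered(self):
        M = pd.DataFrame([[1, 0, 0]] * 5 + [[0, 1, 1]] * 4,
                         index=[f"o{i}" for i in range(9)])
        a = hcluster(binary_distance(M), 2)
        labels = a.labels
        assert labels.iloc[:5].nunique() == 1
        assert labels.iloc[5:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[5]

    def test_k_equals_n_singletons(self):
        rng = np.random.default_rng(3)
        M = pd.DataFrame(rng.integers(0, 2, size=(6, 10)))
        a = hcluster(binary_distance(M), 6)
        assert a.labels.nunique() == 6

    def test_k_out_of_range_rejected(self):
        M = pd.DataFrame([[1, 0], [0, 1]])
        with pytest.raises(ValueError):
            hcluster(binary_distance(M), 3)

    def test_labels_invariant_to_object_order_up_to_relabeling(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(4)
        M = pd.DataFrame(
            np.vstack([rng.binomial(1, 0.9, size=(8, 6)) * [1, 1, 1, 0, 0, 0],
                       rng.binomial(1, 0.9, size=(8, 6)) * [0, 0, 0, 1, 1, 1]]),
            index=[f"o{i}" for i in range(16)])
        a1 = hcluster(binary_distance(M), 2).labels
        perm = rng.permutation(len(M))
        M2 = M.iloc[perm]
        a2 = hcluster(binary_distance(M2), 2).labels
        common = list(M.index)
        assert adjusted_rand_score(a1.loc[common], a2.loc[common]) == 1.0


class TestAssociateRules:
    def assignment(self):
        labels = pd.Series([1] * 10 + [2] * 5,
                           index=[f"o{i}" for i in range(15)], name="cluster")
        return ClusterAssignment(labels=labels, k=2,
                                 linkage_matrix=np.empty((0, 4)),
                                 method="precomputed")

    def test_boundary_inclusive_at_threshold(self):
        r = make_rule({"o0"})  # 1 of 10 members of cluster 1
        m = associate_rules_to_clusters([r], self.assignment(),
                                        threshold_frac=0.10)
        assert m["R001"] == {1}

    def test_below_threshold_excluded(self):
        r = make_rule({"o0"})
        m = associate_rules_to_clusters([r], self.assignment(),
                                        threshold_frac=0.20)
        assert m["R001"] == set()

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(5)
        a = self.assignment()
        rules = [make_rule(set(rng.choice(a.labels.index, size=4,
                                          replace=False)), gene=f"g{i}")
                 for i in range(8)]
        m = associate_rules_to_clusters(rules, a, threshold_frac=0.25)
        for j, r in enumerate(rules):
            for c in (1, 2):
                members = set(a.members(c))
                frac = len(r.support_set & members) / len(members)
                assert (c in m[f"R{j+1:03d}"]) == (frac >= 0.25)


class TestPermutationValidate:
    def table(self):
        rng = np.random.default_rng(6)
        X = np.vstack([np.full((10, 2), 3), np.full((10, 2), 1)])
        X[:, 1] = rng.integers(1, 4, 20)
        return DecisionTable([f"o{i}" for i in range(20)], ["g0", "g1"], X,
                             np.array(["DA3"] * 10 + ["DA1"] * 10,
                                      dtype=object))

    def test_observed_equal_null_mean_not_significant(self):
        calls = iter(range(1000))

        def runner(t):
            next(calls)
            return 0.5 if True else 0.0

        # constant runner: null sd = 0 -> z undefined, flagged not raised
        res = permutation_validate(runner, self.table(), n_perm=10, seed=0)
        assert res.z is None and not res.significant

    def test_signal_detected_at_z_threshold(self):
        from copredict.rules import cross_validate

        def runner(t):
            return cross_validate(t, folds=4, seed=1).accuracy

        res = permutation_validate(runner, self.table(), n_perm=30, seed=1)
        assert res.observed == 1.0
        assert res.z is not None and res.z >= 1.96 and res.significant

    def test_compat_mode_uses_one_sd_band(self):
        vals = iter([0.55] + [0.5 + 0.01 * ((-1) ** i) for i in range(60)])

        def runner(t):
            return next(vals)

        res = permutation_validate(runner, self.table(), n_perm=60, seed=2,
                                   mode="compat")
        # observed 0.55 lies outside null mean 0.5 +/- sd (~0.01)
        assert res.significant


class TestPhenotypeStatistics:
    def assignment(self, labels):
        idx = [f"o{i}" for i in range(len(labels))]
        return ClusterAssignment(labels=pd.Series(labels, index=idx,
                                                  name="cluster"),
                                 k=len(set(labels)),
                                 linkage_matrix=np.empty((0, 4)),
                                 method="precomputed")

    def test_identical_groups_anova_f_zero_p_one(self):
        a = self.assignment([1] * 4 + [2] * 4)
        vals = [1.0, 2.0, 3.0, 4.0] * 2
        pheno = pd.DataFrame({"x": vals}, index=a.labels.index)
        out = cluster_phenotype_tests(a, pheno)
        row = out[(out["test"] == "anova")].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_tukey_equal_means_adjusted_p_near_one(self):
        rng = np.random.default_rng(7)
        a = self.assignment([1] * 10 + [2] * 10 + [3] * 10)
        base = rng.normal(0, 1, 10)
        pheno = pd.DataFrame({"x": np.concatenate([base, base, base])},
                             index=a.labels.index)
        out = cluster_phenotype_tests(a, pheno)
        tuk = out[out["test"] == "tukey"]
        assert (tuk["p_value"] > 0.9).all()

    def test_fisher_cross_table_example(self):
        # separation [[5,0],[0,5]] -> two-sided p = 2/252
        a = self.assignment([1] * 5 + [2] * 5)
        pheno = pd.DataFrame({"flag": [1] * 5 + [0] * 5},
                             index=a.labels.index)
        out = cluster_phenotype_tests(a, pheno)
        p = out[out["comparison"] == "C1 vs rest"]["p_value"].iloc[0]
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_constant_phenotype_skipped(self):
        a = self.assignment([1] * 4 + [2] * 4)
        pheno = pd.DataFrame({"x": [3.0] * 8}, index=a.labels.index)
        out = cluster_phenotype_tests(a, pheno)
        assert len(out) == 0

    def test_rule_wilcoxon_exact_example(self):
        # supported {1,2,3} vs non-supported {101,102,103}: exact p = 0.1
        objects = [f"o{i}" for i in range(6)]
        r = make_rule({"o0", "o1", "o2"})
        pheno = pd.DataFrame({"x": [1.0, 2.0, 3.0, 101.0, 102.0, 103.0]},
                             index=objects)
        per_rule, _ = rule_phenotype_tests([r], pheno, objects)
        assert per_rule["p_value"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_fraction_significant_per_cluster(self):
        objects = [f"o{i}" for i in range(8)]
        rng = np.random.default_rng(8)
        rules = [make_rule({"o0", "o1"}, gene="a"),
                 make_rule({"o2", "o3"}, gene="b"),
                 make_rule({"o4", "o5"}, gene="c"),
                 make_rule({"o0", "o5"}, gene="d")]
        pheno = pd.DataFrame({"x": [0, 0, 5, 5, 5, 5, 0, 0]},
                             index=objects, dtype=float)
        r2c = {"R001": {1}, "R002": {1}, "R003": {1}, "R004": {1}}
        per_rule, per_cluster = rule_phenotype_tests(rules, pheno, objects,
                                                     rule_to_cluster=r2c,
                                                     alpha=0.5)
        row = per_cluster[(per_cluster["cluster"] == 1)
                          & (per_cluster["phenotype"] == "x")].iloc[0]
        n_sig = per_rule["significant"].sum()
        assert row["fraction_significant"] == pytest.approx(n_sig / 4)

    def test_null_rule_contrasts_reject_at_nominal_rate(self):
        rng = np.random.default_rng(9)
        objects = [f"o{i}" for i in range(60)]
        pheno = pd.DataFrame({"x": rng.normal(0, 1, 60)}, index=objects)
        rules = [make_rule(set(rng.choice(objects, 20, replace=False)),
                           gene=f"g{i}") for i in range(200)]
        per_rule, _ = rule_phenotype_tests(rules, pheno, objects)
        rate = per_rule["significant"].mean()
        assert rate == pytest.approx(0.05, abs=0.04)
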