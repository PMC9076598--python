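"""Patient subgroup discovery from rule-support patterns, and the
statistics linking clusters and rules to clinical phenotypes.

The binary support matrix (visits x rules, 1 = visit matches the rule's
IF-part) is clustered hierarchically under the asymmetric binary
(Jaccard) distance; rules are assigned to the clusters whose member
visits they cover.  Continuous phenotypes are compared across clusters by
one-way ANOVA with Tukey HSD post-hocs, binary phenotypes by Fisher's
exact test; per rule, supported vs non-supported visits are contrasted
with a Wilcoxon rank-sum (continuous) or Fisher (binary) test.  Model
significance is assessed by permuting the decision labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, fisher_exact, mannwhitneyu
from sklearn.metrics import silhouette_score
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .rules import DecisionTable, Rule

log = logging.getLogger(__name__)


def rule_ids(rules: list[Rule]) -> list[str]:
    """Stable rule identifiers R001.. in list order."""
    return [f"R{i + 1:03d}" for i in range(len(rules))]


def support_matrix(rules: list[Rule], objects: list[str]) -> pd.DataFrame:
    """Binary objects x rules membership matrix (1 = object supports rule)."""
    ids = rule_ids(rules)
    M = pd.DataFrame(0, index=pd.Index(objects, name="visit_id"),
                     columns=ids, dtype=np.int8)
    for rid, r in zip(ids, rules):
        hit = [o for o in objects if o in r.support_set]
        M.loc[hit, rid] = 1
    zero = M.index[(M.sum(axis=1) == 0)]
    if len(zero):
        log.warning("support_matrix: %d objects support no rule: %s",
                    len(zero), list(zero[:5]))
    return M


def binary_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise asymmetric binary distance between matrix rows.

    d(x, y) = (# columns where exactly one of x,y is 1) /
              (# columns where at least one is 1),
    with d = 0 when no column is active in either row (logged convention).
    """
    if len(matrix) < 2:
        raise ValueError("need >= 2 objects")
    A = matrix.to_numpy(dtype=np.float64)
    ones = A.sum(axis=1)
    inter = A @ A.T
    union = ones[:, None] + ones[None, :] - inter
    discord = union - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, discord / np.maximum(union, 1e-300), 0.0)
    if (union == 0).any():
        log.info("binary_distance: %d pairs share no active column; d=0 used",
                 int(((union == 0).sum() - (union.diagonal() == 0).sum()) // 2))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class ClusterAssignment:
    """Object -> cluster label (1..k) plus the linkage record."""

    labels: pd.Series
    k: int
    linkage_matrix: np.ndarray
    method: str
    rule_to_cluster: dict[str, set[int]] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    @property
    def clusters(self) -> list[int]:
        return sorted(self.labels.unique())


def hcluster(distances: pd.DataFrame, k: int,
             method: str = "complete") -> ClusterAssignment:
    """Agglomerative clustering of a precomputed distance matrix, cut at k."""
    n = len(distances)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range [2, {n}]")
    if method not in ("complete", "average", "ward"):
        raise ValueError(f"unsupported linkage {method!r}")
    condensed = squareform(distances.to_numpy(), checks=False)
    Z = linkage(condensed, method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=distances.index, name="cluster"),
        k=int(labels.max()), linkage_matrix=Z, method=method)


def suggest_k(distances: pd.DataFrame, k_min: int = 2, k_max: int = 8,
              method: str = "complete") -> pd.DataFrame:
    """Mean silhouette width per candidate k, as a k-selection aid."""
    rows = []
    D = distances.to_numpy()
    for k in range(k_min, min(k_max, len(distances) - 1) + 1):
        a = hcluster(distances, k, method=method)
        if a.labels.nunique() < 2:
            continue
        score = silhouette_score(D, a.labels.to_numpy(), metric="precomputed")
        rows.append({"k": k, "silhouette": float(score)})
    return pd.DataFrame(rows)


def associate_rules_to_clusters(rules: list[Rule],
                                assignment: ClusterAssignment,
                                threshold_frac: float = 0.10) -> dict[str, set[int]]:
    """Rule r joins cluster c iff its support covers >= threshold_frac of
    c's members (boundary inclusive); a rule may join several clusters."""
    ids = rule_ids(rules)
    out: dict[str, set[int]] = {}
    members = {c: set(assignment.members(c)) for c in assignment.clusters}
    for rid, r in zip(ids, rules):
        clusters = {
            c for c, mem in members.items()
            if mem and len(r.support_set & mem) / len(mem) >= threshold_frac
        }
        out[rid] = clusters
    assignment.rule_to_cluster = out
    return out


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float | None
    significant: bool
    null_accuracies: np.ndarray


def permutation_validate(runner: Callable[[DecisionTable], float],
                         table: DecisionTable, n_perm: int = 1000,
                         z_threshold: float = 1.96, seed: int = 0,
                         mode: str = "z") -> PermutationResult:
    """Permute decision labels n_perm times, rebuild models, and compare the
    observed accuracy to the null accuracy distribution.

    mode="z": significant iff |observed - mean| / sd >= z_threshold.
    mode="compat": significant iff observed lies outside mean +/- 1 sd
    (a looser historical convention, provided for comparability).
    """
    rng = np.random.default_rng(seed)
    observed = runner(table)
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = table.y.copy()
        rng.shuffle(y_perm)
        nulls[b] = runner(DecisionTable(table.objects, table.features,
                                        table.X, y_perm))
    mean, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    if sd == 0:
        log.warning("permutation_validate: null SD is 0; z undefined")
        z = None
        significant = observed != mean if mode == "compat" else False
    elif mode == "z":
        z = (observed - mean) / sd
        significant = abs(z) >= z_threshold
    elif mode == "compat":
        z = (observed - mean) / sd
        significant = observed < mean - sd or observed > mean + sd
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PermutationResult(observed=observed, null_mean=mean, null_sd=sd,
                             z=z, significant=significant,
                             null_accuracies=nulls)


def _is_binary(values: pd.Series) -> bool:
    u = set(pd.unique(values.dropna()))
    return u <= {0, 1, 0.0, 1.0, True, False}


def cluster_phenotype_tests(assignment: ClusterAssignment,
                            phenotypes: pd.DataFrame,
                            adjust: bool = False) -> pd.DataFrame:
    """Phenotype vs cluster association tests.

    Continuous phenotypes: one-way ANOVA across clusters plus Tukey HSD
    adjusted pairwise p-values.  Binary phenotypes: per cluster, Fisher's
    exact test of the 2x2 (in-cluster vs rest) x (present vs absent)
    table.  Constant phenotypes are skipped with a log entry.  With
    ``adjust``, Benjamini-Hochberg is applied across the ANOVA/Fisher
    p-values (off by default).
    """
    pheno = phenotypes.loc[phenotypes.index.intersection(assignment.labels.index)]
    labels = assignment.labels.loc[pheno.index]
    rows = []
    for col in pheno.columns:
        vals = pheno[col].dropna()
        if vals.nunique() <= 1:
            log.info("cluster_phenotype_tests: %s constant, skipped", col)
            continue
        lab = labels.loc[vals.index]
        if _is_binary(vals):
            for c in assignment.clusters:
                inn = vals[lab == c]
                out = vals[lab != c]
                if len(inn) == 0 or len(out) == 0:
                    continue
                tab = [[int((inn == 1).sum()), int((inn == 0).sum())],
                       [int((out == 1).sum()), int((out == 0).sum())]]
                _, p = fisher_exact(tab, alternative="two-sided")
                rows.append({"phenotype": col, "test": "fisher",
                             "comparison": f"C{c} vs rest",
                             "statistic": np.nan, "p_value": float(p)})
        else:
            groups = [vals[lab == c].to_numpy() for c in assignment.clusters]
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) < 2:
                continue
            F, p = f_oneway(*groups)
            if np.isnan(F):  # all groups identical within -> no variance
                F, p = 0.0, 1.0
            rows.append({"phenotype": col, "test": "anova",
                         "comparison": "all clusters",
                         "statistic": float(F), "p_value": float(p)})
            tuk = pairwise_tukeyhsd(vals.to_numpy(), lab.to_numpy())
            res = tuk.summary().data[1:]
            for r in res:
                rows.append({"phenotype": col, "test": "tukey",
                             "comparison": f"C{r[0]} vs C{r[1]}",
                             "statistic": float(r[2]),
                             "p_value": float(r[3])})
    df = pd.DataFrame(rows, columns=["phenotype", "test", "comparison",
                                     "statistic", "p_value"])
    if adjust and len(df):
        main = df["test"].isin(["anova", "fisher"])
        if main.any():
            df.loc[main, "p_value"] = multipletests(
                df.loc[main, "p_value"], method="fdr_bh")[1]
    return df


def rule_phenotype_tests(rules: list[Rule], phenotypes: pd.DataFrame,
                         objects: list[str],
                         rule_to_cluster: dict[str, set[int]] | None = None,
                         alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-rule supported vs non-supported phenotype contrasts.

    Continuous phenotypes use the two-sided Wilcoxon rank-sum test, binary
    ones Fisher's exact test.  Returns (per-rule results, per-cluster
    fraction of associated rules significant per phenotype); the fraction
    table is empty when no rule-to-cluster map is supplied.
    """
    ids = rule_ids(rules)
    pheno = phenotypes.loc[[o for o in objects if o in phenotypes.index]]
    rows = []
    for rid, r in zip(ids, rules):
        supported = [o for o in pheno.index if o in r.support_set]
        unsupported = [o for o in pheno.index if o not in r.support_set]
        if not supported or not unsupported:
            log.info("rule_phenotype_tests: %s skipped (empty contrast)", rid)
            continue
        for col in pheno.columns:
            a = pheno.loc[supported, col].dropna()
            b = pheno.loc[unsupported, col].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            if _is_binary(pheno[col]):
                tab = [[int((a == 1).sum()), int((a == 0).sum())],
                       [int((b == 1).sum()), int((b == 0).sum())]]
                _, p = fisher_exact(tab, alternative="two-sided")
                test = "fisher"
                stat = np.nan
            else:
                if a.nunique() <= 1 and b.nunique() <= 1 and set(a) == set(b):
                    continue
                stat, p = mannwhitneyu(a, b, alternative="two-sided")
                test = "wilcoxon"
                stat = float(stat)
            rows.append({"rule": rid, "phenotype": col, "test": test,
                         "statistic": stat, "p_value": float(p),
                         "significant": bool(p <= alpha)})
    per_rule = pd.DataFrame(rows, columns=["rule", "phenotype", "test",
                                           "statistic", "p_value", "significant"])
    frac_rows = []
    if rule_to_cluster:
        clusters = sorted({c for s in rule_to_cluster.values() for c in s})
        for c in clusters:
            assoc = [rid for rid in ids if c in rule_to_cluster.get(rid, set())]
            sub = per_rule[per_rule["rule"].isin(assoc)]
            for col in pheno.columns:
                tested = sub[sub["phenotype"] == col]
                if len(tested) == 0:
                    continue
                frac_rows.append({
                    "cluster": c, "phenotype": col,
                    "n_rules": int(tested["rule"].nunique()),
                    "fraction_significant": float(
                        tested["significant"].sum() / len(tested)),
                })
    per_cluster = pd.DataFrame(frac_rows, columns=["cluster", "phenotype",
                                                   "n_rules",
                                                   "fraction_significant"])
    return per_rule, per_cluster
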