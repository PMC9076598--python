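"""Monte Carlo feature selection on discretized decision tables.

Many small decision trees are grown on random feature subsets; each
feature accumulates a relative importance (RI) score

    RI_g = sum over trees tau  (wAcc_tau)^u *
           sum over nodes of tau splitting on g  IG(node) * (n_node/n_tau)^v

where wAcc is the tree's class-balanced accuracy on its held-out split
and IG the information gain of the node's split.  Trees split multiway on
the categorical codes (no pruning, unlimited depth), so RI is invariant
under any relabeling of the {1,2,3} symbols.  A label-permutation test
converts RIs into per-gene p-values (add-one smoothing) from which the
significant gene set is cut.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .rules import DecisionTable


@dataclass
class McfsParams:
    """Knobs of the Monte Carlo feature selection procedure.

    s random feature subsets of size m, t train/test splits per subset
    (2/3 train), importance exponents u and v, n_perm label permutations
    for the significance cutoff at level alpha.  ``m=None`` means
    ceil(sqrt(n_genes)).
    """

    s: int = 3000
    m: int | None = None
    t: int = 5
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 2 / 3
    n_perm: int = 100
    alpha: float = 0.05
    seed: int = 0

    def validate(self, n_features: int) -> None:
        if self.s * self.t < 1:
            raise ValueError("s*t must be >= 1")
        if self.m is not None and self.m > n_features:
            raise ValueError(f"m={self.m} exceeds n_features={n_features}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")

    def resolved_m(self, n_features: int) -> int:
        return self.m if self.m is not None else min(
            n_features, math.ceil(math.sqrt(n_features)))

    def replace(self, **kw) -> "McfsParams":
        d = self.__dict__ | kw
        return McfsParams(**d)


@dataclass
class FeatureRanking:
    """Per-gene RI, rank (1 = most important) and permutation p-value."""

    table: pd.DataFrame  # index gene; columns RI, rank, p_value, significant
    tree_log: list[tuple[float, dict[int, float]]] = field(default_factory=list)

    @property
    def genes_by_rank(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def significant_genes(self) -> list[str]:
        sig = self.table[self.table["significant"]]
        return list(sig.sort_values("rank").index)


@njit(cache=True)
def _tree_kernel(Xtr, ytr, Xte, n_classes, n_levels, v):
    """Grow one multiway information-gain tree and predict the held-out
    objects.  Returns (per-feature IG contribution, test predictions)."""
    n, m = Xtr.shape
    max_nodes = 2 * n + 8
    feat = np.full(max_nodes, -1, np.int32)
    maj = np.zeros(max_nodes, np.int32)
    children = np.full((max_nodes, n_levels), -1, np.int32)
    contrib = np.zeros(m, np.float64)
    idx = np.arange(n)
    stack_node = np.empty(max_nodes, np.int32)
    stack_lo = np.empty(max_nodes, np.int32)
    stack_hi = np.empty(max_nodes, np.int32)
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    top = 1
    n_nodes = 1
    ln2 = np.log(2.0)
    while top > 0:
        top -= 1
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        nn = hi - lo
        ccnt = np.zeros(n_classes, np.int64)
        for i in range(lo, hi):
            ccnt[ytr[idx[i]]] += 1
        best_c = 0
        for c in range(1, n_classes):
            if ccnt[c] > ccnt[best_c]:
                best_c = c
        maj[node] = best_c
        h_parent = 0.0
        for c in range(n_classes):
            if ccnt[c] > 0:
                p = ccnt[c] / nn
                h_parent -= p * np.log(p) / ln2
        if h_parent <= 0.0:
            continue
        best_gain = 0.0
        best_f = -1
        for f in range(m):
            lvl_cls = np.zeros((n_levels, n_classes), np.int64)
            for i in range(lo, hi):
                lvl_cls[Xtr[idx[i], f], ytr[idx[i]]] += 1
            h_child = 0.0
            n_parts = 0
            for l in range(n_levels):
                ln = 0
                for c in range(n_classes):
                    ln += lvl_cls[l, c]
                if ln > 0:
                    n_parts += 1
                    hl = 0.0
                    for c in range(n_classes):
                        if lvl_cls[l, c] > 0:
                            p = lvl_cls[l, c] / ln
                            hl -= p * np.log(p) / ln2
                    h_child += ln / nn * hl
            if n_parts > 1:
                g = h_parent - h_child
                if g > best_gain + 1e-12:
                    best_gain = g
                    best_f = f
        if best_f < 0:
            continue
        feat[node] = best_f
        contrib[best_f] += best_gain * (nn / n) ** v
        cnt = np.zeros(n_levels, np.int64)
        for i in range(lo, hi):
            cnt[Xtr[idx[i], best_f]] += 1
        starts = np.zeros(n_levels + 1, np.int64)
        for l in range(n_levels):
            starts[l + 1] = starts[l] + cnt[l]
        tmp = np.empty(nn, np.int64)
        pos = starts[:n_levels].copy()
        for i in range(lo, hi):
            l = Xtr[idx[i], best_f]
            tmp[pos[l]] = idx[i]
            pos[l] += 1
        for i in range(nn):
            idx[lo + i] = tmp[i]
        for l in range(n_levels):
            if cnt[l] > 0:
                child = n_nodes
                n_nodes += 1
                children[node, l] = child
                stack_node[top] = child
                stack_lo[top] = lo + starts[l]
                stack_hi[top] = lo + starts[l + 1]
                top += 1
    pred = np.empty(Xte.shape[0], np.int32)
    for i in range(Xte.shape[0]):
        node = 0
        while feat[node] >= 0:
            c = children[node, Xte[i, feat[node]]]
            if c < 0:
                break
            node = c
        pred[i] = maj[node]
    return contrib, pred


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray,
                       n_classes: int) -> float:
    accs = []
    for c in range(n_classes):
        mask = y_true == c
        if mask.any():
            accs.append(float((y_pred[mask] == c).mean()))
    return float(np.mean(accs)) if accs else 0.0


def rank_features(table: DecisionTable, params: McfsParams,
                  keep_tree_log: bool = False) -> FeatureRanking:
    """Monte Carlo RI ranking of all features of a decision table.

    Deterministic given ``params.seed``.  With ``keep_tree_log`` each
    tree's (wAcc, per-feature contribution) pair is retained so the RI sum
    can be audited term by term.
    """
    n_feat = len(table.features)
    params.validate(n_feat)
    classes = table.classes
    if len(classes) < 2:
        raise ValueError("decision table has a single class")
    if min(table.class_counts().values()) < 2:
        raise ValueError("every class needs >= 2 objects")
    m = params.resolved_m(n_feat)
    rng = np.random.default_rng(params.seed)
    cls_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray([cls_index[c] for c in table.y], dtype=np.int64)
    X = np.ascontiguousarray(table.X, dtype=np.int64)
    n_obj, n_classes = len(y), len(classes)
    n_train = max(2, int(round(params.train_fraction * n_obj)))
    n_train = min(n_train, n_obj - 1)
    n_levels = int(X.max()) + 1

    ri = np.zeros(n_feat)
    tree_log: list[tuple[float, dict[int, float]]] = []
    order = np.arange(n_obj)
    for _ in range(params.s):
        feats = rng.choice(n_feat, size=m, replace=False)
        Xsub = np.ascontiguousarray(X[:, feats])
        for _ in range(params.t):
            rng.shuffle(order)
            tr, te = order[:n_train], order[n_train:]
            if len(np.unique(y[tr])) < 2:
                continue
            contrib, pred = _tree_kernel(Xsub[tr], y[tr], Xsub[te],
                                         n_classes, n_levels, params.v)
            wacc = _balanced_accuracy(y[te], pred, n_classes)
            w = wacc ** params.u
            ri[feats] += w * contrib
            if keep_tree_log:
                nz = np.nonzero(contrib)[0]
                tree_log.append(
                    (wacc, {int(feats[j]): float(contrib[j]) for j in nz}))

    df = pd.DataFrame({"RI": ri}, index=pd.Index(table.features, name="gene"))
    # rank 1 = highest RI; ties broken by gene name for determinism
    df["rank"] = (
        df.sort_values(["RI", "gene"], ascending=[False, True])
        .assign(r=lambda d: np.arange(1, len(d) + 1))["r"]
        .reindex(df.index)
    )
    df["p_value"] = np.nan
    df["significant"] = False
    return FeatureRanking(table=df, tree_log=tree_log)


def significance_cutoff(ranking: FeatureRanking, table: DecisionTable,
                        params: McfsParams) -> list[str]:
    """Label-permutation significance cutoff for the ranked list.

    For each gene, p = (1 + #{permuted RI >= observed RI}) / (1 + n_perm);
    significant iff p <= alpha.  Updates ``ranking.table`` in place and
    returns the significant genes in rank order.
    """
    if params.n_perm < 20:
        warnings.warn(f"n_perm={params.n_perm} < 20 gives unstable p-values",
                      stacklevel=2)
    rng = np.random.default_rng(params.seed + 7919)
    observed = ranking.table["RI"].to_numpy()
    exceed = np.zeros(len(observed), dtype=int)
    for _ in range(params.n_perm):
        y_perm = table.y.copy()
        rng.shuffle(y_perm)
        perm_table = DecisionTable(table.objects, table.features, table.X,
                                   y_perm)
        perm_seed = int(rng.integers(0, 2**31 - 1))
        perm_ri = rank_features(
            perm_table, params.replace(seed=perm_seed)).table["RI"].to_numpy()
        exceed += perm_ri >= observed
    p = (1 + exceed) / (1 + params.n_perm)
    ranking.table["p_value"] = p
    ranking.table["significant"] = p <= params.alpha
    return ranking.significant_genes()
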