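"""Model enhancement: pruning unmatched visits, feature boosting, and
diagnostics of what kind of visit gets pruned.

Pruning removes every object whose codes match the IF-part of no
significant rule of the current model — the visits the rule model cannot
speak about.  Feature boosting then scans prefixes of the (re-ranked)
gene list, cross-validating a rule model on each prefix, and selects the
smallest prefix attaining the maximal accuracy, optionally followed by a
backward-elimination pass.  The pruning diagnostics regress the removal
indicator on clinical covariates to make the pruned-away subpopulation
explicit.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rules import DecisionTable, RuleModel, cross_validate

log = logging.getLogger(__name__)


def prune_unclassified(table: DecisionTable, model: RuleModel,
                       alpha: float = 0.05) -> tuple[DecisionTable, list[str]]:
    """Drop objects matched by no rule with p_value < alpha.

    Returns the pruned table and the removed object IDs.  Idempotent:
    re-pruning the pruned table with the same model removes nothing.
    Raises if pruning would empty a decision class.
    """
    sig = model.significant_rules(alpha)
    feat_index = {f: j for j, f in enumerate(table.features)}
    matched = np.zeros(table.n_objects, dtype=bool)
    for r in sig:
        mask = np.ones(table.n_objects, dtype=bool)
        for d in r.lhs:
            j = feat_index.get(d.gene)
            if j is None:
                raise KeyError(f"model gene {d.gene} absent from table")
            mask &= table.X[:, j] == d.level
        matched |= mask
    removed_idx = np.nonzero(~matched)[0]
    removed = [table.objects[i] for i in removed_idx]
    kept = np.nonzero(matched)[0]
    kept_classes = Counter(table.y[kept])
    for c in set(table.y):
        if kept_classes.get(c, 0) == 0:
            raise ValueError(f"pruning would remove every object of class {c}")
    per_class = Counter(table.y[removed_idx])
    log.info("prune_unclassified: removed %d/%d objects (%s)",
             len(removed), table.n_objects, dict(per_class))
    return table.subset_objects(kept), removed


@dataclass
class BoostTrace:
    """Accuracy per gene-prefix size; the selected (minimal) gene set."""

    sizes: list[int]
    accuracies: list[float]
    selected_genes: list[str]
    selected_size: int
    eliminated: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_genes": self.sizes, "cv_accuracy": self.accuracies})


def feature_boost(ranked_genes: list[str], table: DecisionTable,
                  max_genes: int = 200, folds: int = 10, seed: int = 0,
                  step: int = 1, n_reducts: int = 10, repeats: int = 1,
                  fallback: str = "abstain",
                  backward_elimination: bool = False) -> BoostTrace:
    """Incrementally add ranked genes; pick the smallest prefix with
    maximal cross-validated accuracy.

    ``step`` thins the prefix grid for large rankings (size 1, 1+step,
    ...).  ``repeats`` averages each prefix's accuracy over several CV
    fold seeds, damping the fold-assignment noise that otherwise decides
    ties on a flat accuracy plateau.  The selection metric defaults to
    abstention-aware accuracy (``fallback="abstain"``): a held-out visit
    matched by no rule, or tied between classes, counts as an error, so
    the selected panel must cover the cohort with decisive rules rather
    than lean on the majority-class fallback.  With
    ``backward_elimination`` a single pass then drops genes whose removal
    does not reduce CV accuracy, giving a locally minimal set.
    """
    if not ranked_genes:
        raise ValueError("empty gene ranking")
    missing = [g for g in ranked_genes if g not in table.features]
    if missing:
        raise KeyError(f"ranked genes absent from table: {missing[:10]}")
    limit = min(max_genes, len(ranked_genes))
    sizes = list(range(1, limit + 1, step))
    if sizes[-1] != limit:
        sizes.append(limit)
    accs = []
    for size in sizes:
        sub = table.subset_features(ranked_genes[:size])
        accs.append(float(np.mean([
            cross_validate(sub, folds=folds, seed=seed + 1000 * r,
                           n_reducts=n_reducts, fallback=fallback).accuracy
            for r in range(repeats)])))
    best = max(accs)
    sel_i = min(i for i, a in enumerate(accs) if a == best)
    selected = list(ranked_genes[: sizes[sel_i]])
    eliminated: list[str] = []
    if backward_elimination and len(selected) > 1:
        current_acc = accs[sel_i]
        for g in list(reversed(selected)):
            trial = [x for x in selected if x != g]
            if not trial:
                break
            acc = cross_validate(table.subset_features(trial), folds=folds,
                                 seed=seed, n_reducts=n_reducts,
                                 fallback=fallback).accuracy
            if acc >= current_acc:
                selected = trial
                eliminated.append(g)
                current_acc = acc
    return BoostTrace(sizes=sizes, accuracies=accs, selected_genes=selected,
                      selected_size=len(selected), eliminated=eliminated)


def pruning_diagnostics(removed: pd.Series,
                        covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Logistic regression of the removal indicator on covariates.

    Returns one row per covariate (plus intercept) with coefficient, odds
    ratio and Wald p-value.  Perfect separation is flagged with NaN
    p-values rather than raised.
    """
    y = removed.astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one removed and one kept object")
    if covariates is None or covariates.shape[1] == 0:
        X = pd.DataFrame(index=y.index)
    else:
        X = covariates.loc[y.index].astype(float)
    X = sm.add_constant(X, has_constant="add")
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params, pvals = fit.params, fit.pvalues
        bse = fit.bse
        if not np.isfinite(bse).all() or (np.abs(params) > 30).any():
            separated = True
    except Exception:  # PerfectSeparationError or convergence failure
        separated = True
        params = pd.Series(np.nan, index=X.columns)
        pvals = pd.Series(np.nan, index=X.columns)
    if separated:
        pvals = pd.Series(np.nan, index=X.columns)
    out = pd.DataFrame({
        "coefficient": params,
        "odds_ratio": np.exp(params),
        "p_value": pvals,
    })
    out["separation_flag"] = separated
    return out
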