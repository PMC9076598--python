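"""Rough-set rule induction on discretized decision tables.

A decision table holds visits (objects) x genes (features) with codes in
{1,2,3} and a decision class per object.  Reducts — minimal feature
subsets preserving discernibility between objects of different classes —
are found either exhaustively (small tables) or with a randomized Johnson
greedy hitting-set heuristic.  Overlaying reducts on the objects yields
IF-THEN rules whose quality is measured by support, accuracy, coverage
and a hypergeometric (Fisher-type) upper-tail p-value.  Classification is
by support*accuracy-weighted voting, evaluated with stratified k-fold
cross-validation.
"""

from __future__ import annotations

import hashlib
import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.model_selection import StratifiedKFold

EXHAUSTIVE_FEATURE_LIMIT = 20


@dataclass(frozen=True, order=True)
class Descriptor:
    """A (gene, discretized level) pair — one conjunct of a rule's IF-part."""

    gene: str
    level: int

    def __post_init__(self) -> None:
        if self.level not in (1, 2, 3):
            raise ValueError(f"invalid code level {self.level}")

    def __str__(self) -> str:
        return f"{self.gene}={self.level}"


@dataclass(frozen=True)
class Rule:
    """IF conjunction-of-descriptors THEN decision, with quality measures.

    ``support_set`` is every object matching the IF-part regardless of its
    class; ``accuracy`` the fraction of those in the rule's class;
    ``coverage`` the support relative to the size of the rule's class.
    """

    lhs: tuple[Descriptor, ...]
    decision: str
    support_set: frozenset[str]
    support: int
    accuracy: float
    coverage: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.lhs:
            raise ValueError("rule IF-part must be non-empty")
        genes = [d.gene for d in self.lhs]
        if len(set(genes)) != len(genes):
            raise ValueError("two descriptors share a gene")
        if self.support != len(self.support_set):
            raise ValueError("support != |support_set|")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(d.gene for d in self.lhs)

    def matches(self, codes: dict[str, int]) -> bool:
        return all(codes[d.gene] == d.level for d in self.lhs)

    def __str__(self) -> str:
        lhs = " AND ".join(str(d) for d in self.lhs)
        return f"IF {lhs} THEN {self.decision}"


@dataclass
class DecisionTable:
    """Objects x discrete features with a decision column."""

    objects: list[str]
    features: list[str]
    X: np.ndarray  # (n_objects, n_features) int codes
    y: np.ndarray  # (n_objects,) class labels (str)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.shape != (len(self.objects), len(self.features)):
            raise ValueError(f"X shape {self.X.shape} does not match "
                             f"{len(self.objects)} objects x {len(self.features)} features")
        if len(self.y) != len(self.objects):
            raise ValueError("decision vector length mismatch")

    @classmethod
    def from_frames(cls, coded: pd.DataFrame, labels: pd.Series) -> "DecisionTable":
        """Build from a genes x visits coded matrix and a visit->class series."""
        visits = list(coded.columns)
        missing = [v for v in visits if v not in labels.index]
        if missing:
            raise ValueError(f"visits without a decision label: {missing[:10]}")
        return cls(objects=visits, features=list(coded.index),
                   X=coded.to_numpy(dtype=np.int8).T,
                   y=labels.loc[visits].to_numpy(dtype=object))

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.y))

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(self.y))

    def majority_class(self) -> str:
        counts = self.class_counts()
        best = max(counts.values())
        return sorted(c for c, n in counts.items() if n == best)[0]

    def subset_features(self, features: list[str]) -> "DecisionTable":
        idx = [self.features.index(f) for f in features]
        return DecisionTable(self.objects, list(features), self.X[:, idx], self.y)

    def subset_objects(self, idx: np.ndarray) -> "DecisionTable":
        idx = np.asarray(idx)
        return DecisionTable([self.objects[i] for i in idx], self.features,
                             self.X[idx], self.y[idx])

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.objects).encode())
        h.update(repr(self.features).encode())
        h.update(self.X.tobytes())
        h.update(repr(list(self.y)).encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------- reducts

def _discernibility_entries(table: DecisionTable) -> np.ndarray:
    """Boolean (n_entries, n_features) matrix: one deduplicated row per
    cross-class object pair, True where the pair's codes differ.  Pairs with
    identical feature vectors (inconsistent table) yield empty entries and
    are dropped — the generalized-decision convention."""
    X, y = table.X, table.y
    rows = []
    n = len(y)
    for i in range(n):
        diff_cls = np.nonzero(y[i + 1:] != y[i])[0] + i + 1
        if len(diff_cls) == 0:
            continue
        d = X[diff_cls] != X[i]
        rows.append(d[d.any(axis=1)])
    if not rows:
        return np.zeros((0, len(table.features)), dtype=bool)
    entries = np.concatenate(rows, axis=0)
    return np.unique(entries, axis=0)


def _covers(entries: np.ndarray, subset: tuple[int, ...]) -> bool:
    if entries.shape[0] == 0:
        return True
    return bool(entries[:, list(subset)].any(axis=1).all())


def compute_reducts(table: DecisionTable, method: str = "johnson",
                    n_reducts: int = 10, seed: int = 0,
                    candidate_frac: float = 0.3) -> list[tuple[str, ...]]:
    """Find (approximate) reducts of a decision table.

    ``exhaustive`` enumerates all minimal hitting sets of the
    discernibility matrix (refused above 20 features); ``johnson`` runs
    the randomized greedy maximum-coverage heuristic: at each step one of
    the attributes covering at least ``candidate_frac`` of the best
    attribute's uncovered entries is drawn with probability proportional
    to its coverage, followed by a redundancy-elimination pass so every
    returned set is a minimal hitting set.  Up to ``n_reducts`` distinct
    reducts are collected; deterministic given ``seed``.
    ``candidate_frac=1.0`` reduces to classic Johnson with random
    tie-breaking only.  A constant-decision table returns ``[()]``.
    """
    entries = _discernibility_entries(table)
    n_feat = len(table.features)
    if entries.shape[0] == 0:
        return [()]

    if method == "exhaustive":
        if n_feat > EXHAUSTIVE_FEATURE_LIMIT:
            raise ValueError(
                f"exhaustive reducts refused for {n_feat} > "
                f"{EXHAUSTIVE_FEATURE_LIMIT} features")
        found: list[tuple[int, ...]] = []
        for size in range(1, n_feat + 1):
            for subset in itertools.combinations(range(n_feat), size):
                if any(set(r) <= set(subset) for r in found):
                    continue
                if _covers(entries, subset):
                    found.append(subset)
        reducts = sorted(found)
        return [tuple(table.features[i] for i in r) for r in reducts]

    if method != "johnson":
        raise ValueError(f"unknown reduct method {method!r}")

    rng = np.random.default_rng(seed)
    out: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    attempts = 0
    max_attempts = max(4 * n_reducts, 20)
    while len(out) < n_reducts and attempts < max_attempts:
        attempts += 1
        uncovered = np.ones(entries.shape[0], dtype=bool)
        chosen: list[int] = []
        while uncovered.any():
            counts = entries[uncovered].sum(axis=0).astype(float)
            best = counts.max()
            cands = np.nonzero(counts >= candidate_frac * best)[0]
            pick = int(rng.choice(cands, p=counts[cands] / counts[cands].sum()))
            chosen.append(pick)
            uncovered &= ~entries[:, pick]
        # redundancy elimination -> minimal hitting set
        for a in sorted(chosen):
            rest = tuple(c for c in chosen if c != a)
            if rest and _covers(entries, rest):
                chosen = list(rest)
        key = tuple(sorted(chosen))
        if key not in seen:
            seen.add(key)
            out.append(key)
    return [tuple(table.features[i] for i in r) for r in out]


def compute_object_reducts(table: DecisionTable, seed: int = 0,
                           candidate_frac: float = 0.3) -> list[tuple[str, ...]]:
    """Object-related (local) reducts: for every object, a minimal feature
    set discerning it from all discernible objects of the other classes,
    found with the randomized Johnson greedy.  Returns one reduct per
    object, aligned with ``table.objects`` (empty tuple when nothing
    discerns the object)."""
    X, y = table.X, table.y
    rng = np.random.default_rng(seed)
    out: list[tuple[int, ...]] = []
    for i in range(table.n_objects):
        diff = np.nonzero(y != y[i])[0]
        entries = X[diff] != X[i]
        entries = entries[entries.any(axis=1)]
        if entries.shape[0] == 0:
            out.append(())
            continue
        entries = np.unique(entries, axis=0)
        uncovered = np.ones(entries.shape[0], dtype=bool)
        chosen: list[int] = []
        while uncovered.any():
            counts = entries[uncovered].sum(axis=0).astype(float)
            best = counts.max()
            cands = np.nonzero(counts >= candidate_frac * best)[0]
            pick = int(rng.choice(cands, p=counts[cands] / counts[cands].sum()))
            chosen.append(pick)
            uncovered &= ~entries[:, pick]
        for a in sorted(chosen):
            rest = tuple(c for c in chosen if c != a)
            if rest and _covers(entries, rest):
                chosen = list(rest)
        out.append(tuple(sorted(chosen)))
    return [tuple(table.features[f] for f in r) for r in out]


def induce_object_rules(table: DecisionTable,
                        object_reducts: list[tuple[str, ...]]) -> list[Rule]:
    """One rule per object from its local reduct: the IF-part is the
    object's own descriptor values on its reduct; identical IF-parts
    merge.  Quality measures are computed against the full table exactly
    as in :func:`induce_rules`."""
    if len(object_reducts) != table.n_objects:
        raise ValueError("need one reduct per object")
    N = table.n_objects
    class_sizes = table.class_counts()
    order = {c: (-class_sizes[c], c) for c in class_sizes}
    feat_index = {f: j for j, f in enumerate(table.features)}
    rules: dict[tuple[Descriptor, ...], Rule] = {}
    for i, reduct in enumerate(object_reducts):
        if not reduct:
            continue
        lhs = tuple(sorted(Descriptor(f, int(table.X[i, feat_index[f]]))
                           for f in reduct))
        if lhs in rules:
            continue
        mask = np.ones(N, dtype=bool)
        for d in lhs:
            mask &= table.X[:, feat_index[d.gene]] == d.level
        members = np.nonzero(mask)[0]
        counts = Counter(table.y[members])
        best = max(counts.values())
        decision = min((c for c, n in counts.items() if n == best),
                       key=lambda c: order[c])
        support = len(members)
        k = counts[decision]
        rules[lhs] = Rule(
            lhs=lhs, decision=decision,
            support_set=frozenset(table.objects[j] for j in members),
            support=support,
            accuracy=k / support,
            coverage=support / class_sizes[decision],
            p_value=rule_pvalue_counts(N, class_sizes[decision], support, k),
        )
    return sorted(rules.values(), key=lambda r: r.lhs)


# ----------------------------------------------------------------- rules

def rule_pvalue_counts(N: int, K: int, n: int, k: int) -> float:
    """Hypergeometric upper tail P(X >= k) for a rule matching n objects of
    which k are in the rule's class (K of N objects in the class)."""
    if n == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def rule_pvalue(rule: Rule, table: DecisionTable) -> float:
    """Recompute a rule's significance against a table by brute matching."""
    match = _match_mask(rule, table)
    n = int(match.sum())
    k = int((table.y[match] == rule.decision).sum())
    K = int((table.y == rule.decision).sum())
    return rule_pvalue_counts(table.n_objects, K, n, k)


def _match_mask(rule: Rule, table: DecisionTable) -> np.ndarray:
    mask = np.ones(table.n_objects, dtype=bool)
    for d in rule.lhs:
        j = table.features.index(d.gene)
        mask &= table.X[:, j] == d.level
    return mask


def induce_rules(table: DecisionTable,
                 reducts: list[tuple[str, ...]]) -> list[Rule]:
    """Generate IF-THEN rules by overlaying reducts on the objects.

    For every (object, reduct) the object's values on the reduct form the
    IF-part; the decision is the majority class among all objects matching
    that IF-part (ties to the overall larger class, then lexicographic).
    Duplicate IF-parts merge.  Quality measures are computed against the
    full table.
    """
    N = table.n_objects
    class_sizes = table.class_counts()
    order = {c: (-class_sizes[c], c) for c in class_sizes}
    rules: dict[tuple[Descriptor, ...], Rule] = {}
    feat_index = {f: j for j, f in enumerate(table.features)}
    for reduct in reducts:
        if not reduct:
            continue
        cols = [feat_index[f] for f in reduct]
        sub = table.X[:, cols]
        uniq, inv = np.unique(sub, axis=0, return_inverse=True)
        for gi in range(len(uniq)):
            lhs = tuple(sorted(Descriptor(f, int(v))
                               for f, v in zip(reduct, uniq[gi])))
            if lhs in rules:
                continue
            members = np.nonzero(inv == gi)[0]
            counts = Counter(table.y[members])
            best = max(counts.values())
            decision = min((c for c, n in counts.items() if n == best),
                           key=lambda c: order[c])
            support = len(members)
            k = counts[decision]
            rules[lhs] = Rule(
                lhs=lhs, decision=decision,
                support_set=frozenset(table.objects[i] for i in members),
                support=support,
                accuracy=k / support,
                coverage=support / class_sizes[decision],
                p_value=rule_pvalue_counts(N, class_sizes[decision], support, k),
            )
    return sorted(rules.values(), key=lambda r: r.lhs)


@dataclass
class RuleModel:
    """A trained rule set with provenance."""

    rules: list[Rule]
    majority_class: str
    fingerprint: str = ""
    cv_accuracy: float | None = None

    @property
    def class_rule_counts(self) -> dict[str, int]:
        return dict(Counter(r.decision for r in self.rules))

    def significant_rules(self, alpha: float = 0.05) -> list[Rule]:
        return [r for r in self.rules if r.p_value < alpha]


def train_model(table: DecisionTable, method: str = "object",
                n_reducts: int = 10, seed: int = 0) -> RuleModel:
    """Train a rule model.  ``method="object"`` derives one local reduct
    (and hence one rule) per object, mirroring the object-related setting
    of classic rough-set toolchains; ``"johnson"``/``"exhaustive"`` use
    table-wide reducts applied to every object."""
    if method == "object":
        rules = induce_object_rules(table,
                                    compute_object_reducts(table, seed=seed))
    else:
        reducts = compute_reducts(table, method=method, n_reducts=n_reducts,
                                  seed=seed)
        rules = induce_rules(table, reducts)
    return RuleModel(rules=rules, majority_class=table.majority_class(),
                     fingerprint=table.fingerprint())


ABSTAIN = "<abstain>"


def classify(codes: dict[str, int], model: RuleModel,
             fallback: str = "majority") -> str:
    """Vote all matching rules with weight support*accuracy.

    Ties and no-match fall back to the training majority class (default)
    or to abstention.  Classification is invariant to rule order.
    """
    needed = {d.gene for r in model.rules for d in r.lhs}
    unknown = sorted(needed - set(codes))
    if unknown:
        raise KeyError(f"object lacks codes for genes used by rules: {unknown[:10]}")
    votes: Counter[str] = Counter()
    for r in model.rules:
        if r.matches(codes):
            votes[r.decision] += r.support * r.accuracy
    if votes:
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
            return ranked[0][0]
    if fallback == "majority":
        return model.majority_class
    if fallback == "abstain":
        return ABSTAIN
    raise ValueError(f"unknown fallback {fallback!r}")


def classify_table(table: DecisionTable, model: RuleModel,
                   fallback: str = "majority") -> list[str]:
    """Vectorized voting over all objects of a table."""
    needed = {d.gene for r in model.rules for d in r.lhs}
    unknown = sorted(needed - set(table.features))
    if unknown:
        raise KeyError(f"table lacks genes used by rules: {unknown[:10]}")
    feat_index = {f: j for j, f in enumerate(table.features)}
    classes = sorted({r.decision for r in model.rules} | {model.majority_class})
    votes = np.zeros((table.n_objects, len(classes)))
    cidx = {c: i for i, c in enumerate(classes)}
    for r in model.rules:
        mask = np.ones(table.n_objects, dtype=bool)
        for d in r.lhs:
            mask &= table.X[:, feat_index[d.gene]] == d.level
        votes[mask, cidx[r.decision]] += r.support * r.accuracy
    out = []
    for i in range(table.n_objects):
        v = votes[i]
        top = v.max()
        winners = [classes[j] for j in range(len(classes)) if v[j] == top]
        if top > 0 and len(winners) == 1:
            out.append(winners[0])
        elif fallback == "majority":
            out.append(model.majority_class)
        else:
            out.append(ABSTAIN)
    return out


@dataclass
class CVResult:
    accuracy: float
    fold_accuracies: list[float]
    fold_sizes: list[int]


def cross_validate(table: DecisionTable, folds: int = 10, seed: int = 0,
                   method: str = "object", n_reducts: int = 10,
                   fallback: str = "majority") -> CVResult:
    """Stratified k-fold CV: reducts and rules induced on the training
    portion only; overall accuracy is the mean of per-fold accuracies.
    Abstentions (fallback="abstain") count as errors."""
    counts = table.class_counts()
    too_small = {c: n for c, n in counts.items() if n < folds}
    if too_small:
        raise ValueError(
            f"classes smaller than folds={folds}: {too_small}; use fewer folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, sizes = [], []
    y_codes = pd.factorize(pd.Series(table.y))[0]
    for f, (tr, te) in enumerate(skf.split(table.X, y_codes)):
        model = train_model(table.subset_objects(tr), method=method,
                            n_reducts=n_reducts, seed=seed + 1000 + f)
        pred = classify_table(table.subset_objects(te), model, fallback=fallback)
        accs.append(float(np.mean([p == t for p, t in zip(pred, table.y[te])])))
        sizes.append(len(te))
    return CVResult(accuracy=float(np.mean(accs)), fold_accuracies=accs,
                    fold_sizes=sizes)
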