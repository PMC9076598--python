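# Methods

This note documents the models, numerical conventions and design
choices behind `copredict`, in the spirit of a statistical software
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and synthetic cohorts

The unit of analysis is the *clinic visit*, not the patient: one
patient contributes 1–15 visits, each labelled control, DA1 (low
disease activity, SLEDAI 0–2) or DA3 (high activity, SLEDAI > 7).
Expression values are continuous log-scale intensities, genes × visits.

The generator (`copredict.simulate`) draws, per gene, a control
distribution Normal(μ_g, σ_g) with μ_g ~ U(5, 10) and σ_g ~ U(0.3, 1.2)
— log₂-microarray-like magnitudes. Class-informative genes are shifted
by ±δ·σ_g in every DA3 visit (the sign fixed per gene at generation, so
both up- and down-regulated genes occur); subgroup-informative genes are
shifted only in the visits of one planted DA3 subgroup; all other genes
are identically distributed in every class. Default cohort: 60
controls, 150 DA1, 150 DA3 visits split into two 75-visit subgroups,
1000 genes of which 20 are class-informative and 10 per subgroup, with
δ = 2.5. Phenotypes are generated *conditionally on class/subgroup*
(not on expression): SLEDAI uniform in the class-defining range,
continuous labs Normal with per-subgroup additive shifts, binary
symptoms Bernoulli with per-subgroup rates. Phenotype distributions are
package choices — the underlying study reports none — and exist so that
phenotype-recovery tests are well-posed.

What the generator does *not* emulate: probe-level bead-chip artifacts,
longitudinal autocorrelation within a patient, heavy-tailed or skewed
intensity noise, and covariance between genes beyond the planted
shifts. Tests passing on this generator therefore demonstrate
correctness of the machinery and recoverability of planted structure
under Gaussian noise, not performance on real microarray data.

A batch covariate is emitted (`batch_count` labels); when
`batch_effect_sd > 0` an additive per-(batch, gene) offset is applied.
The only correction supplied is a per-batch mean-centering stub
(`preprocess.center_batches`); surrogate-variable-style correction is
out of scope.

## Discretization

Per gene, the control mean μ and *sample* SD σ (denominator n−1) define
the coding: code 1 iff x ≤ μ − 2σ, code 3 iff x ≥ μ + 2σ, code 2
otherwise. Conventions:

- Low wins at exact equality with μ − 2σ (boundary inclusive below).
- The upper threshold is μ + 2σ. (A description of this scheme in
  circulation writes the High bound with a minus sign; that would make
  Medium empty, so it is treated as a typo.)
- σ = 0 genes (constant controls) are kept, coding 2 only at exactly μ
  and 1/3 by sign of the deviation otherwise.
- The log base for `log_transform` is 2 by default, configurable.

The coding is invariant under any strictly increasing affine transform
applied jointly to data and controls (property-tested).

## Monte Carlo feature selection

RI_g = Σ over trees τ (wAcc_τ)^u · Σ over nodes of τ splitting on g
IG(node) · (n_node/n_τ)^v, with defaults u = v = 1, s subsets of
m = ⌈√(#genes)⌉ features, t = 5 train/test splits per subset (2/3
train). wAcc is class-balanced accuracy on the held-out third. The
trees split *multiway on the categorical codes* with information gain,
unlimited depth, no pruning: with ≤ 3 levels per feature the trees stay
small, and multiway splits make RI exactly invariant under relabelling
of the code symbols (binary threshold splits would not be). The tree
kernel is compiled with numba; a per-tree contribution log lets tests
audit the RI sum to 1e-10.

Significance: decision labels are permuted n_perm times, the whole
ranking recomputed, and per gene p = (1 + #{permuted RI ≥ observed RI})
/ (1 + n_perm) (add-one smoothing, so p is never 0 and an observed RI
of 0 gives p = 1); significant iff p ≤ α = 0.05. n_perm < 20 triggers
an instability warning because min p = 1/(n_perm+1) must reach α.

## Reducts and rules

The discernibility matrix holds, for every cross-class visit pair, the
set of genes on which their codes differ; pairs with identical code
vectors (inconsistent tables) contribute nothing (generalized-decision
convention). Three reduct modes:

- `exhaustive` — all minimal hitting sets, by subset enumeration with
  superset pruning; refused above 20 features; used as the oracle
  anchor in tests.
- `johnson` — randomized greedy hitting set. At each step the
  candidates are the attributes covering ≥ `candidate_frac` (default
  0.3) of the best attribute's uncovered entries, drawn with
  probability proportional to coverage; a redundancy-elimination pass
  then makes the output a *minimal* hitting set. With
  `candidate_frac = 1.0` this reduces to classic Johnson with random
  tie-breaking only — which, on realistic tables where exact coverage
  ties are rare, would return essentially one reduct; the probabilistic
  candidate pool is what yields a diverse reduct sample.
- `object` (pipeline default) — object-related local reducts: for each
  visit, a minimal gene set discerning *it* from all discernible visits
  of the other class, via the same randomized greedy. One rule per
  visit (duplicates merged) mirrors the object-related setting of
  classic rough-set toolchains and produces the rich, diverse rule
  repertoires that the downstream network and clustering stages need.
  In particular, for a visit in a molecular subgroup its own strongly
  shifted genes discern it as well as globally class-informative genes
  do, so subgroup descriptors enter the rule set systematically —
  table-wide greedy reducts, dominated by the globally strongest genes,
  leave subgroup structure invisible to the support matrix.

Rule quality against the full training table: support = all matching
visits; accuracy = fraction of those in the rule's class (majority
class on inconsistent IF-parts, ties to the larger class then
lexicographic); coverage = support / class size; significance =
hypergeometric upper tail P(X ≥ k | N, K, n) — a Fisher-type
enrichment of the rule's class within its matches.

Classification: all matching rules vote with weight support × accuracy;
ties and unmatched objects fall back to the training majority class by
default, or to an explicit abstention. Cross-validation is stratified
k-fold (k = 10 default), reducts and rules re-induced on each training
fold, overall accuracy the mean of fold accuracies.

## Model enhancement

Pruning removes visits matched by no rule with p < α from the *initial*
model (training-set p-values, not refit). Removal counts per class are
logged, and a logistic regression of the removal indicator on clinical
covariates (statsmodels, Wald p-values; perfect separation flagged
rather than raised) documents who gets pruned.

Feature boosting scans gene-list prefixes 1..max_genes in rank order,
cross-validating a rule model on each prefix, and selects the smallest
prefix attaining the maximal accuracy (exact ties always break to the
smaller prefix). Two numerical choices matter on strong-signal data
where the trace plateaus near 1:

- each prefix's accuracy is averaged over `repeats` CV fold-seeds
  (default 2 in the pipeline), damping fold-assignment noise that would
  otherwise place the maximum at an arbitrary plateau position;
- the selection metric is *abstention-aware* (a held-out visit matched
  by no rule, or tied, counts as an error), so the selected panel must
  cover the cohort with decisive rules instead of leaning on the
  majority-class fallback. The final model is still evaluated with the
  standard majority fallback.

An optional backward-elimination pass (off by default) drops genes
whose removal does not reduce accuracy. The boosting does not re-run
MCFS between increments.

## Rule networks

One network per decision class. Nodes are descriptors (gene, level) of
the kept rules — rules of that class with coverage ≥ 10 % and p ≤ 0.05;
a gene can therefore appear with different levels in the two class
networks. Node attributes: number of supporting visits (union of the
kept rules' support sets) and number of rules. Edge connection =
Σ coverage·accuracy over kept rules whose IF-part contains both
descriptors, max-normalized to percent within the class network (the
strongest edge is exactly 100 when any edge exists). "Connection" has
no published closed form; this definition reproduces the intended
semantics — strength of co-appearance in rules supporting a class — on
a percent scale. Cluster membership of rules can be projected onto
nodes as per-node composition fractions. Export: GraphML (networkx)
and a flat TSV edge list; both round-trip.

## Subgroup discovery and statistics

The support matrix has kept visits as rows, significant rules of the
subgroup model as columns, cells 1 iff the visit matches the rule's
IF-part. By default (`subgroup_source="significant"`) the subgroup
model is trained on the top `max_model_genes` MCFS-*ranked* genes of
the pruned table, not on the boost-minimal panel: a minimal
discriminative panel is by construction blind to within-class
heterogeneity once the class signal saturates, whereas subgroup
structure lives in the wider rule repertoire. The ranked list rather
than the permutation-significant list is used here because the cutoff's
pass/fail resolution is 1/(n_perm+1) — at modest permutation counts it
can drop borderline subgroup-informative genes wholesale — while the
rank order of those genes is stable; the significance gate is kept
where parsimony matters (classification models, reported rankings).

Distance: asymmetric binary (Jaccard) distance, d = discordant /
active columns, with d = 0 for two all-zero profiles (logged
convention). Clustering: scipy agglomerative linkage, *average* by
default — under the heavy ties this distance produces, complete linkage
can fail to split the cohort at all, while average linkage behaves
well; scipy's own deterministic tie-breaking is used rather than a
bespoke lexicographic merge rule. k is supplied by config or suggested
by mean silhouette width. Two robustness conventions in the pipeline:
visits supporting no rule are excluded from clustering (their distance
profile is degenerate), and the dendrogram cut is deepened until k
clusters of at least `min_cluster_size` (default 3) members exist, so
stray outlier visits in singleton branches do not consume cut levels.

Rules join a cluster when their support covers ≥ 10 % (boundary
inclusive) of the cluster's members — the 20 % variant is a config
preset. Continuous phenotypes are compared across clusters by one-way
ANOVA plus Tukey HSD adjusted pairwise p-values; binary phenotypes per
cluster by Fisher's exact test on the 2×2 in-cluster vs rest table.
Per rule, supported vs non-supported visits are contrasted with a
two-sided Wilcoxon rank-sum test (continuous; exact for small samples)
or Fisher's exact test (binary); per cluster the fraction of associated
rules significant at p ≤ 0.05 is reported. Raw p-values are used by
default for fidelity to the original workflow; Benjamini–Hochberg is
available as an option. (A published description assigns the Wilcoxon
test to "categorical" variables; that is read as *continuous*, with
binary variables going to Fisher.)

Model validation permutes the decision labels n_perm times, rebuilds
the model each time (via a caller-supplied runner returning CV
accuracy), and compares the observed accuracy to the null distribution.
Default rule: significant iff |z| ≥ 1.96 with z = (obs − mean)/SD. A
compatibility mode reproduces the looser historical convention
(outside mean ± 1 SD ⇒ "p < 0.05"), which does not correspond to a 95 %
normal interval; both are provided without asserting which the original
analysis used. A zero null SD is flagged, z undefined.

## Pipeline, determinism and problem sizes

`run_pipeline` executes discretize → MCFS → initial model → prune →
MCFS → boost → enhanced model → networks → clustering → associations →
phenotype tests → permutation validation, writing every artifact as
TSV/JSON/GraphML plus a manifest with the config hash and per-stage
counts. All stage seeds are fixed offsets from the config seed (kept
below 2³¹); identical (config, inputs) reproduce the rule JSON and
cluster TSV byte for byte.

Default problem sizes in the packaged configs — MCFS with s = 150
subsets and 20 permutation replicates, boosting over 40 prefixes with
5-fold CV × 2 repeats, validation with 100 permutations — were chosen
so a full synthetic run (360 visits × 1000 genes) completes in about a
minute on one CPU while leaving the planted structure comfortably
recoverable; all are configurable upward for real cohorts.

## Known limitations

- The Gaussian generator understates real microarray noise structure;
  recovery rates reported by the acceptance script are upper bounds on
  what identical settings would achieve on real data.
- Approximate (randomized) reducts carry no optimality guarantee beyond
  minimality as hitting sets.
- On strong-signal data the boost trace is flat near its maximum, and
  the smallest-maximal-prefix rule then selects a panel whose exact
  size is partly stochastic; the repeats/abstention conventions above
  reduce but do not remove this.
- Inconsistent decision tables are handled by majority decision, not by
  boundary-region rules.
- Batch correction is a mean-centering stub; use dedicated tools for
  real multi-batch data.
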