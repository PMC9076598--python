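# copredict

Interpretable rule-based modelling of disease-activity transcriptomes:
rough-set rule induction, co-prediction rule networks, and patient
subgroup discovery from rule-support patterns.

## The problem

Bulk blood transcriptomes of patients with a relapsing autoimmune
disease such as paediatric systemic lupus erythematosus (SLE) are
heterogeneous: the same clinical severity class (low disease activity,
SLEDAI 0–2, "DA1"; high activity, SLEDAI > 7, "DA3") hides distinct
molecular subgroups, and single-gene differential expression misses the
*combinations* of genes that jointly discriminate the classes.
`copredict` re-implements a transparent alternative to black-box
classifiers:

1. **Discretization against the healthy controls.** For each gene g the
   control mean μ_g and SD σ_g define three levels:
   Low (1) if x ≤ μ_g − 2σ_g, High (3) if x ≥ μ_g + 2σ_g, Medium (2)
   otherwise. A patient visit becomes a vector of codes in {1,2,3}.
2. **Monte Carlo feature selection (MCFS).** Thousands of small decision
   trees on random gene subsets score each gene's relative importance
   RI_g = Σ_τ (wAcc_τ)^u · Σ_{nodes on g} IG(node)·(n_node/n_τ)^v,
   with a label-permutation cutoff (p ≤ 0.05) for significance.
3. **Rough-set rule induction.** Reducts — minimal gene sets preserving
   discernibility between DA1 and DA3 visits — are overlaid on the
   visits to produce IF–THEN rules such as
   `IF G00123=3 AND G00456=2 THEN DA3`, each with support, accuracy,
   coverage and a hypergeometric p-value. Rules vote
   (weight = support × accuracy) to classify new visits; performance is
   estimated by stratified 10-fold cross-validation.
4. **Model enhancement.** Visits matched by no significant rule are
   pruned, genes re-ranked, and *feature boosting* scans prefixes of the
   ranking to find the smallest gene panel with maximal cross-validated
   accuracy.
5. **Co-prediction rule networks.** Per decision class, descriptors
   (gene, level) become nodes; descriptors co-occurring in a rule's
   IF-part are joined by edges whose strength sums coverage × accuracy
   over shared rules (max-normalized to percent).
6. **Subgroup discovery.** The binary visits × rules support matrix is
   clustered hierarchically under the asymmetric binary (Jaccard)
   distance; clusters are tested against clinical phenotypes (ANOVA +
   Tukey HSD, Fisher exact, Wilcoxon rank-sum) and validated by
   permuting the decision labels.

A fully parameterised synthetic-cohort generator with known ground truth
(informative genes, planted DA3 subgroups, phenotype–subgroup
correlations) makes every stage testable without external data.

## Worked example

```python
from copredict import PipelineConfig, SimConfig, run_pipeline

config = PipelineConfig(sim=SimConfig(seed=11), mcfs_s=150, mcfs_n_perm=20,
                        folds=10, n_clusters=3, seed=11)
results = run_pipeline(config, "runs/demo")
sizes = results["assignment"].labels.value_counts().sort_index()
print(f"initial CV accuracy  {results['initial_cv_accuracy']:.3f}")
print(f"enhanced CV accuracy {results['enhanced_cv_accuracy']:.3f}")
print(f"selected gene panel  {results['boost_trace'].selected_size} genes")
print(f"rules per class      {results['enhanced_model'].class_rule_counts}")
print(f"clusters             {[int(n) for n in sizes]}")
```

On the default synthetic cohort (60 controls, 150 DA1 and 150 DA3
visits, 1000 genes, effect size 2.5 control SDs) this prints:

```
initial CV accuracy  0.997
enhanced CV accuracy 0.987
selected gene panel  31 genes
rules per class      {'DA1': 136, 'DA3': 107}
clusters             [150, 75, 75]
```

meaning the rule model separates the two activity classes essentially
perfectly at this effect size, boosting compresses the panel to 31
genes, and clustering the rule-support matrix splits the cohort into
the DA1 block and the two planted 75-visit DA3 subgroups. The run
directory
contains every artifact (coded matrix, rankings, rule JSON/TSV, GraphML
networks, cluster and phenotype tables, run manifest).

The same pipeline is scriptable from the shell:

```bash
copredict simulate --out runs/sim --seed 11
copredict run-all --out runs/full --seed 11
```

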