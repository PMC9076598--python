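"""End-to-end orchestration of the rule-based analysis.

Stage order: discretize -> feature selection -> initial rule model ->
prune unmatched visits -> re-select -> feature boost -> enhanced model ->
rule networks -> support-matrix clustering -> rule/cluster association ->
phenotype tests -> permutation validation.  Every stage writes a
plain-text artifact into the run directory and a manifest records
parameters, seeds and per-stage counts; a rerun with identical config and
inputs reproduces the directory byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .bundle import DA1, DA3, ExpressionBundle
from .mcfs import McfsParams, rank_features, significance_cutoff
from .network import build_network, export_network, project_clusters
from .preprocess import discretize, fit_discretizer, log_transform
from .refine import feature_boost, prune_unclassified, pruning_diagnostics
from .rules import DecisionTable, cross_validate, train_model
from .simulate import SimConfig, generate
from .subgroups import (associate_rules_to_clusters, binary_distance,
                        cluster_phenotype_tests, hcluster,
                        permutation_validate, rule_phenotype_tests,
                        rule_ids, suggest_k, support_matrix)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single config object driving :func:`run_pipeline`.

    ``sim`` is a :class:`SimConfig` (synthetic input); alternatively
    ``expression_path``/``meta_path`` point at TSV inputs.  Stage toggles
    and per-stage parameters mirror the module functions; every stage's
    randomness derives from ``seed``.
    """

    # input
    sim: SimConfig | None = None
    expression_path: str | None = None
    meta_path: str | None = None
    values_are_logged: bool = True
    log_base: float = 2.0

    # feature selection
    mcfs_s: int = 300
    mcfs_m: int | None = None
    mcfs_t: int = 5
    mcfs_n_perm: int = 30
    mcfs_alpha: float = 0.05
    max_model_genes: int = 100   # cap on genes fed to rule models

    # rule induction / evaluation: "object" = one local reduct per visit
    reduct_method: str = "object"
    n_reducts: int = 10
    folds: int = 10
    rule_alpha: float = 0.05

    # refinement
    do_prune: bool = True
    do_boost: bool = True
    boost_max_genes: int = 40
    boost_step: int = 1
    boost_folds: int = 5
    boost_repeats: int = 2
    backward_elimination: bool = False

    # networks
    do_networks: bool = True
    network_min_support_frac: float = 0.10
    network_alpha: float = 0.05

    # clustering / associations
    do_clusters: bool = True
    # "significant": cluster rule supports of the full significant-gene
    # model (subgroup structure needs the whole rule repertoire);
    # "enhanced": cluster the minimal boosted model's rule supports
    subgroup_source: str = "significant"
    subgroup_n_reducts: int = 60
    n_clusters: int | None = None  # None -> silhouette suggestion
    min_cluster_size: int = 3  # cut deeper until k clusters reach this size
    linkage_method: str = "average"
    association_threshold: float = 0.10

    # validation
    do_validate: bool = False
    validation_n_perm: int = 100
    validation_mode: str = "z"
    z_threshold: float = 1.96

    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict() if self.sim else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim"):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(cio._plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _mcfs_params(cfg: PipelineConfig, seed: int) -> McfsParams:
    return McfsParams(s=cfg.mcfs_s, m=cfg.mcfs_m, t=cfg.mcfs_t,
                      n_perm=cfg.mcfs_n_perm, alpha=cfg.mcfs_alpha, seed=seed)


def _ranking_tsv(ranking, path: Path) -> None:
    ranking.table.to_csv(path, sep="\t", index_label="gene")


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 resume: bool = False) -> dict:
    """Execute the full analysis; returns a result dictionary and writes
    all artifacts under ``outdir``.

    With ``resume=True`` stages whose artifact files already exist are
    reloaded instead of recomputed, so deleted downstream artifacts can be
    regenerated from upstream ones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config_hash": config.config_hash(), "stages": {}}
    results: dict = {"outdir": str(outdir)}
    cio.write_config(config.to_dict(), outdir / "config.yaml")

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 2),
                                     **cio._plain(info)}
        log.info("stage %s: %s", stage, info)

    # ----- input ----------------------------------------------------------
    expr_path, meta_path = outdir / "expression.tsv", outdir / "meta.tsv"
    if config.sim is not None:
        if resume and expr_path.exists() and meta_path.exists():
            bundle = cio.read_bundle(expr_path, meta_path)
            truth = cio.read_ground_truth(outdir / "truth.json")
        else:
            bundle, truth = generate(config.sim)
            cio.write_bundle(bundle, expr_path, meta_path)
            cio.write_ground_truth(truth, outdir / "truth.json")
        results["truth"] = truth
    else:
        if not (config.expression_path and config.meta_path):
            raise ValueError("config needs either sim or expression/meta paths")
        bundle = cio.read_bundle(config.expression_path, config.meta_path)
        truth = None
    record("input", n_genes=len(bundle.genes), n_visits=len(bundle.visits),
           class_counts=bundle.classes().value_counts().to_dict())

    # ----- preprocess ------------------------------------------------------
    values = bundle.values
    if not config.values_are_logged:
        values = log_transform(values, base=config.log_base)
        bundle = ExpressionBundle(values, bundle.visit_meta, bundle.phenotypes)
    model_path = outdir / "discretizer.tsv"
    disc = fit_discretizer(bundle)
    cio.write_discretizer(disc, model_path)
    da_visits = bundle.visits_of(DA1) + bundle.visits_of(DA3)
    coded = discretize(bundle.values[da_visits], disc)
    cio.write_matrix(coded, outdir / "coded.tsv")
    table = DecisionTable.from_frames(coded, bundle.classes())
    results["table"] = table
    record("discretize", n_objects=table.n_objects,
           class_counts=table.class_counts())

    # ----- initial feature selection --------------------------------------
    params = _mcfs_params(config, config.seed + 11)
    ranking = rank_features(table, params)
    sig = significance_cutoff(ranking, table, params)
    _ranking_tsv(ranking, outdir / "ranking_initial.tsv")
    initial_genes = sig[: config.max_model_genes]
    if not initial_genes:  # no significant gene: fall back to top-ranked
        initial_genes = ranking.genes_by_rank[: config.max_model_genes]
    record("mcfs_initial", n_significant=len(sig),
           n_used=len(initial_genes))
    results["ranking_initial"] = ranking

    # ----- initial model ---------------------------------------------------
    t_init = table.subset_features(initial_genes)
    initial_model = train_model(t_init, method=config.reduct_method,
                                n_reducts=config.n_reducts,
                                seed=config.seed + 23)
    cv_init = cross_validate(t_init, folds=config.folds,
                             seed=config.seed + 29,
                             method=config.reduct_method,
                             n_reducts=config.n_reducts)
    initial_model.cv_accuracy = cv_init.accuracy
    cio.rules_to_json(initial_model.rules, outdir / "rules_initial.json",
                      meta={"cv_accuracy": cv_init.accuracy,
                            "config_hash": config.config_hash()})
    results["initial_model"] = initial_model
    results["initial_cv_accuracy"] = cv_init.accuracy
    record("initial_model", n_rules=len(initial_model.rules),
           cv_accuracy=cv_init.accuracy,
           rules_per_class=initial_model.class_rule_counts)

    # ----- prune -----------------------------------------------------------
    if config.do_prune:
        try:
            pruned, removed = prune_unclassified(t_init, initial_model,
                                                 alpha=config.rule_alpha)
        except ValueError as exc:
            # pruning would empty a class: keep the full table
            log.warning("prune skipped: %s", exc)
            pruned, removed = t_init, []
        pruned = table.subset_objects(
            [table.objects.index(o) for o in pruned.objects])
        pd.Series(removed, name="visit_id").to_csv(
            outdir / "removed.tsv", sep="\t", index=False)
        removed_per_class = pd.Series(
            {o: dict(zip(table.objects, table.y))[o] for o in removed}
        ).value_counts().to_dict() if removed else {}
        if len(bundle.phenotypes):
            flags = pd.Series([o in set(removed) for o in table.objects],
                              index=pd.Index(table.objects), dtype=int)
            covs = bundle.phenotypes.loc[
                flags.index,
                [c for c in bundle.phenotypes.columns
                 if bundle.phenotypes[c].nunique() > 1]]
            if 0 < flags.sum() < len(flags):
                diag = pruning_diagnostics(flags, covs)
                diag.to_csv(outdir / "pruning_diagnostics.tsv", sep="\t",
                            index_label="covariate")
        record("prune", n_removed=len(removed),
               removed_per_class=removed_per_class,
               n_kept=pruned.n_objects)
    else:
        pruned, removed = table, []
    results["pruned_table"] = pruned
    results["removed"] = removed

    # ----- re-selection + boost -------------------------------------------
    params2 = _mcfs_params(config, config.seed + 31)
    ranking2 = rank_features(pruned, params2)
    sig2 = significance_cutoff(ranking2, pruned, params2)
    _ranking_tsv(ranking2, outdir / "ranking_pruned.tsv")
    ranked = (sig2 or ranking2.genes_by_rank)[: config.max_model_genes]
    record("mcfs_pruned", n_significant=len(sig2), n_used=len(ranked))
    results["ranking_pruned"] = ranking2

    if config.do_boost:
        trace = feature_boost(ranked, pruned,
                              max_genes=config.boost_max_genes,
                              folds=config.boost_folds,
                              seed=config.seed + 37,
                              step=config.boost_step,
                              n_reducts=config.n_reducts,
                              repeats=config.boost_repeats,
                              backward_elimination=config.backward_elimination)
        trace.to_frame().to_csv(outdir / "boost_trace.tsv", sep="\t",
                                index=False)
        (outdir / "selected_genes.txt").write_text(
            "\n".join(trace.selected_genes) + "\n")
        selected = trace.selected_genes
        results["boost_trace"] = trace
        record("boost", selected_size=trace.selected_size,
               best_accuracy=max(trace.accuracies))
    else:
        selected = ranked

    # ----- enhanced model ---------------------------------------------------
    t_enh = pruned.subset_features(selected)
    enhanced_model = train_model(t_enh, method=config.reduct_method,
                                 n_reducts=config.n_reducts,
                                 seed=config.seed + 41)
    cv_enh = cross_validate(t_enh, folds=config.folds,
                            seed=config.seed + 43,
                            method=config.reduct_method,
                            n_reducts=config.n_reducts)
    enhanced_model.cv_accuracy = cv_enh.accuracy
    cio.rules_to_json(enhanced_model.rules, outdir / "rules_enhanced.json",
                      meta={"cv_accuracy": cv_enh.accuracy,
                            "config_hash": config.config_hash()})
    cio.rules_to_tsv(enhanced_model.rules, outdir / "rules_enhanced.tsv")
    results["enhanced_model"] = enhanced_model
    results["enhanced_cv_accuracy"] = cv_enh.accuracy
    results["enhanced_table"] = t_enh
    record("enhanced_model", n_rules=len(enhanced_model.rules),
           cv_accuracy=cv_enh.accuracy,
           rules_per_class=enhanced_model.class_rule_counts)

    # ----- networks ---------------------------------------------------------
    networks = {}
    if config.do_networks:
        for cls in (DA1, DA3):
            net = build_network(enhanced_model.rules, cls,
                                min_support_frac=config.network_min_support_frac,
                                alpha=config.network_alpha)
            networks[cls] = net
        record("networks",
               **{f"{c}_nodes": n.n_nodes for c, n in networks.items()},
               **{f"{c}_edges": n.n_edges for c, n in networks.items()})
    results["networks"] = networks

    # ----- clustering + associations ---------------------------------------
    if config.do_clusters:
        if config.subgroup_source == "significant":
            # top-ranked genes, not only those past the permutation cutoff:
            # the cutoff's pass/fail resolution (1/(n_perm+1)) is too coarse
            # for the exploratory subgroup stage and can drop half of a
            # subgroup's informative genes at small n_perm
            sub_genes = ranking2.genes_by_rank[: config.max_model_genes]
            t_sub = pruned.subset_features(sub_genes)
            subgroup_model = train_model(t_sub, method=config.reduct_method,
                                         n_reducts=config.subgroup_n_reducts,
                                         seed=config.seed + 59)
        elif config.subgroup_source == "enhanced":
            t_sub = t_enh
            subgroup_model = enhanced_model
        else:
            raise ValueError(
                f"unknown subgroup_source {config.subgroup_source!r}")
        cluster_rules = subgroup_model.significant_rules(config.rule_alpha)
        if not cluster_rules:
            cluster_rules = subgroup_model.rules
        M = support_matrix(cluster_rules, t_sub.objects)
        M.to_csv(outdir / "support_matrix.tsv", sep="\t")
        # visits supporting no rule have no usable distance profile
        zero_rows = list(M.index[M.sum(axis=1) == 0])
        if zero_rows:
            log.info("clusters: %d visits support no rule, excluded: %s",
                     len(zero_rows), zero_rows[:5])
            M = M.loc[M.sum(axis=1) > 0]
        D = binary_distance(M)
        if config.n_clusters is None:
            sil = suggest_k(D, method=config.linkage_method)
            k = int(sil.loc[sil["silhouette"].idxmax(), "k"]) if len(sil) else 2
        else:
            k = config.n_clusters
        # outlier-robust cut: deepen the cut until k clusters of at least
        # min_cluster_size members exist (stray visits form tiny clusters
        # that would otherwise consume cut levels)
        assignment = hcluster(D, k, method=config.linkage_method)
        kk = k
        while (kk < min(k + 10, len(D))
               and (assignment.labels.value_counts()
                    >= config.min_cluster_size).sum() < k):
            kk += 1
            assignment = hcluster(D, kk, method=config.linkage_method)
        assignment.labels.to_csv(outdir / "clusters.tsv", sep="\t",
                                 index_label="visit_id")
        r2c = associate_rules_to_clusters(cluster_rules, assignment,
                                          threshold_frac=config.association_threshold)
        (outdir / "rule_clusters.json").write_text(json.dumps(
            {rid: sorted(int(c) for c in cs) for rid, cs in r2c.items()},
            indent=1, sort_keys=True))
        results["assignment"] = assignment
        results["support_matrix"] = M
        results["cluster_rules"] = cluster_rules
        record("clusters", k=k, n_cluster_rules=len(cluster_rules),
               sizes=assignment.labels.value_counts().sort_index().to_dict())

        if len(bundle.phenotypes):
            cpt = cluster_phenotype_tests(assignment, bundle.phenotypes)
            cpt.to_csv(outdir / "cluster_phenotypes.tsv", sep="\t", index=False)
            per_rule, per_cluster = rule_phenotype_tests(
                cluster_rules, bundle.phenotypes, t_sub.objects,
                rule_to_cluster=r2c, alpha=config.rule_alpha)
            per_rule.to_csv(outdir / "rule_phenotypes.tsv", sep="\t",
                            index=False)
            per_cluster.to_csv(outdir / "fraction_significant.tsv", sep="\t",
                               index=False)
            results["cluster_phenotypes"] = cpt
            results["rule_phenotypes"] = per_rule
            results["fraction_significant"] = per_cluster
        if networks:
            # project cluster membership of the enhanced model's rules
            enh_r2c = associate_rules_to_clusters(
                enhanced_model.rules, assignment,
                threshold_frac=config.association_threshold)
            name_map = {}
            for rid, r in zip(rule_ids(enhanced_model.rules),
                              enhanced_model.rules):
                name_map[str(r)] = enh_r2c.get(rid, set())
            for cls, net in networks.items():
                project_clusters(net, name_map)
            assignment.rule_to_cluster = r2c
    if config.do_networks:
        for cls, net in networks.items():
            export_network(net, outdir / f"network_{cls}.graphml", "graphml")
            export_network(net, outdir / f"network_{cls}.tsv", "edge-tsv")

    # ----- permutation validation ------------------------------------------
    if config.do_validate:
        def runner(tbl: DecisionTable) -> float:
            return cross_validate(tbl, folds=min(config.folds, 5),
                                  seed=config.seed + 47,
                                  method=config.reduct_method,
                                  n_reducts=max(2, config.n_reducts // 2)
                                  ).accuracy

        perm = permutation_validate(runner, t_enh,
                                    n_perm=config.validation_n_perm,
                                    z_threshold=config.z_threshold,
                                    seed=config.seed + 53,
                                    mode=config.validation_mode)
        (outdir / "validation.json").write_text(json.dumps({
            "observed": perm.observed, "null_mean": perm.null_mean,
            "null_sd": perm.null_sd, "z": perm.z,
            "significant": bool(perm.significant),
            "n_perm": config.validation_n_perm,
        }, indent=1, sort_keys=True))
        results["validation"] = perm
        record("validation", observed=perm.observed, z=perm.z,
               significant=bool(perm.significant))

    (outdir / "manifest.json").write_text(
        json.dumps(cio._plain(manifest), indent=1, sort_keys=True))
    results["manifest"] = manifest
    return results
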