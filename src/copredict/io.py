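"""Readers and writers for the pipeline's plain-text artifact formats.

Everything is TSV, JSON or YAML: expression matrices (genes x visits),
per-visit metadata+phenotype tables, coded matrices, discretizer models,
feature rankings, rule sets and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bundle import META_COLUMNS, ExpressionBundle
from .preprocess import DiscretizationModel
from .rules import Descriptor, Rule
from .simulate import GroundTruth, SimConfig


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t", index_label="gene")
    return path


def read_matrix(path: str | Path, dtype=float) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return df.astype(dtype)
    except ValueError as exc:
        # locate the offending cell for the error message
        for gene, row in df.iterrows():
            for col, v in row.items():
                try:
                    dtype(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"malformed numeric cell at gene={gene}, "
                        f"visit={col}: {v!r}") from exc
        raise


def write_bundle(bundle: ExpressionBundle, expression_path: str | Path,
                 meta_path: str | Path) -> None:
    """Expression as genes x visits TSV; metadata and phenotypes merged
    into one row-per-visit TSV."""
    write_matrix(bundle.values, expression_path)
    meta = bundle.visit_meta.copy()
    if len(bundle.phenotypes):
        meta = meta.join(bundle.phenotypes, how="left")
    meta.to_csv(meta_path, sep="\t", index_label="visit_id")


def read_bundle(expression_path: str | Path,
                meta_path: str | Path) -> ExpressionBundle:
    values = read_matrix(expression_path)
    meta = pd.read_csv(meta_path, sep="\t", index_col="visit_id")
    missing = [v for v in values.columns if v not in meta.index]
    if missing:
        raise ValueError(f"visits missing from metadata: {missing}")
    pheno_cols = [c for c in meta.columns if c not in META_COLUMNS]
    return ExpressionBundle(
        values=values,
        visit_meta=meta[[c for c in META_COLUMNS if c in meta.columns]],
        phenotypes=meta[pheno_cols],
    )


def write_discretizer(model: DiscretizationModel, path: str | Path) -> Path:
    path = Path(path)
    model.to_frame().to_csv(path, sep="\t", index_label="gene")
    return path


def read_discretizer(path: str | Path) -> DiscretizationModel:
    return DiscretizationModel.from_frame(
        pd.read_csv(path, sep="\t", index_col="gene"))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_dict(json.loads(Path(path).read_text()))


def rules_to_json(rules: list[Rule], path: str | Path,
                  meta: dict | None = None) -> Path:
    path = Path(path)
    payload = {
        "meta": meta or {},
        "rules": [
            {
                "lhs": [{"gene": d.gene, "level": d.level} for d in r.lhs],
                "decision": r.decision,
                "support_set": sorted(r.support_set),
                "support": r.support,
                "accuracy": r.accuracy,
                "coverage": r.coverage,
                "p_value": r.p_value,
            }
            for r in rules
        ],
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def rules_from_json(path: str | Path) -> list[Rule]:
    payload = json.loads(Path(path).read_text())
    out = []
    for r in payload["rules"]:
        out.append(Rule(
            lhs=tuple(Descriptor(d["gene"], int(d["level"])) for d in r["lhs"]),
            decision=r["decision"],
            support_set=frozenset(r["support_set"]),
            support=int(r["support"]),
            accuracy=float(r["accuracy"]),
            coverage=float(r["coverage"]),
            p_value=float(r["p_value"]),
        ))
    return out


def rules_to_tsv(rules: list[Rule], path: str | Path) -> Path:
    from .subgroups import rule_ids
    path = Path(path)
    rows = []
    for rid, r in zip(rule_ids(rules), rules):
        rows.append({
            "rule_id": rid,
            "lhs": " AND ".join(str(d) for d in r.lhs),
            "decision": r.decision,
            "support": r.support,
            "accuracy": r.accuracy,
            "coverage": r.coverage,
            "p_value": r.p_value,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_config(config: dict | SimConfig, path: str | Path) -> Path:
    path = Path(path)
    payload = config.to_dict() if isinstance(config, SimConfig) else config
    path.write_text(yaml.safe_dump(_plain(payload), sort_keys=True))
    return path


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _plain(obj):
    """Recursively coerce numpy scalars/tuples so YAML stays readable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
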