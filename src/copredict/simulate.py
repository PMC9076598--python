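"""Synthetic expression cohorts with known ground truth.

Emulates the structure of a whole-blood disease-activity study: healthy
controls plus patient visits in a low (DA1) and a high (DA3) activity
state, repeat visits per patient, batch labels, class-informative genes
shifted in units of the control standard deviation, planted subgroups
inside DA3 with their own informative gene sets, and clinical phenotypes
(SLEDAI, continuous labs, binary symptoms) correlated with class and
subgroup.

Every downstream stage of the pipeline is testable against the returned
:class:`GroundTruth` without any external download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import CONTROL, DA1, DA3, ExpressionBundle


@dataclass(frozen=True)
class PhenotypeSpec:
    """One clinical phenotype and how it depends on class/subgroup.

    ``kind`` is ``"continuous"`` (Normal(mean, sd) plus per-class and
    per-subgroup additive shifts) or ``"binary"`` (Bernoulli with a base
    rate overridden per class/subgroup).  Shift/rate keys may be class
    labels (``DA1``/``DA3``/``control``) or subgroup labels (``S1`` ...).
    """

    name: str
    kind: str  # "continuous" | "binary"
    mean: float = 0.0
    sd: float = 1.0
    rate: float = 0.1
    shifts: dict[str, float] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)


def default_phenotype_specs() -> list[PhenotypeSpec]:
    """Clinically flavoured defaults: labs shifted per DA3 subgroup, plus
    null variables for calibration.  Distributions are package choices; the
    subgroup shifts make phenotype-recovery tests well-posed."""
    return [
        PhenotypeSpec("complement_c3", "continuous", mean=100.0, sd=15.0,
                      shifts={"S1": -35.0, DA3: -5.0}),
        PhenotypeSpec("lymphocyte_pct", "continuous", mean=30.0, sd=6.0,
                      shifts={"S1": 8.0, "S2": -8.0}),
        PhenotypeSpec("wbc", "continuous", mean=7.0, sd=2.0),
        PhenotypeSpec("nephritis", "binary", rate=0.10, rates={"S1": 0.55}),
        PhenotypeSpec("alopecia", "binary", rate=0.15, rates={"S2": 0.50}),
    ]


@dataclass
class SimConfig:
    """Cohort layout and effect sizes for :func:`generate`.

    Defaults describe the canonical test condition: 60 controls, 150 DA1
    and 150 DA3 visits over 1000 genes, 20 class-informative genes and two
    planted 75-visit DA3 subgroups with 10 subgroup-informative genes
    each, at an effect size of 2.5 control SDs.
    """

    n_controls: int = 60
    n_da1: int = 150
    n_da3: int = 150
    n_genes: int = 1000
    n_informative_class: int = 20
    subgroup_sizes: tuple[int, ...] = (75, 75)
    n_informative_per_subgroup: int = 10
    effect_size: float = 2.5
    control_mean_range: tuple[float, float] = (5.0, 10.0)
    control_sd_range: tuple[float, float] = (0.3, 1.2)
    visits_per_patient_range: tuple[int, int] = (1, 15)
    batch_count: int = 2
    batch_effect_sd: float = 0.0
    phenotype_specs: list[PhenotypeSpec] = field(default_factory=default_phenotype_specs)
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_controls=self.n_controls, n_da1=self.n_da1,
                      n_da3=self.n_da3, n_genes=self.n_genes,
                      n_informative_class=self.n_informative_class,
                      n_informative_per_subgroup=self.n_informative_per_subgroup,
                      batch_count=self.batch_count)
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if sum(self.subgroup_sizes) != self.n_da3:
            raise ValueError(
                f"subgroup_sizes {self.subgroup_sizes} do not partition "
                f"n_da3={self.n_da3}")
        if any(s < 0 for s in self.subgroup_sizes):
            raise ValueError("subgroup sizes must be >= 0")
        lo, hi = self.control_sd_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError(f"control_sd_range must be positive, got {self.control_sd_range}")
        lo, hi = self.visits_per_patient_range
        if lo < 1 or hi < lo:
            raise ValueError("visits_per_patient_range must satisfy 1 <= lo <= hi")
        n_inform = (self.n_informative_class
                    + self.n_informative_per_subgroup * len(self.subgroup_sizes))
        if n_inform > self.n_genes:
            raise ValueError("more informative genes requested than genes")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phenotype_specs"] = [dataclasses.asdict(p) for p in self.phenotype_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "phenotype_specs" in d:
            d["phenotype_specs"] = [
                p if isinstance(p, PhenotypeSpec) else PhenotypeSpec(**p)
                for p in d["phenotype_specs"]
            ]
        if "subgroup_sizes" in d:
            d["subgroup_sizes"] = tuple(d["subgroup_sizes"])
        for k in ("control_mean_range", "control_sd_range", "visits_per_patient_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    informative_class_genes: frozenset[str]
    subgroup_genes: dict[str, frozenset[str]]  # subgroup label -> gene set
    class_assignment: dict[str, str]           # visit -> control/DA1/DA3
    subgroup_assignment: dict[str, str]        # DA3 visit -> subgroup label
    shift_signs: dict[str, int]                # informative gene -> +1/-1

    @property
    def informative_gene_ids(self) -> frozenset[str]:
        ids = set(self.informative_class_genes)
        for s in self.subgroup_genes.values():
            ids |= s
        return frozenset(ids)

    def to_dict(self) -> dict:
        return {
            "informative_class_genes": sorted(self.informative_class_genes),
            "subgroup_genes": {k: sorted(v) for k, v in self.subgroup_genes.items()},
            "class_assignment": self.class_assignment,
            "subgroup_assignment": self.subgroup_assignment,
            "shift_signs": self.shift_signs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            informative_class_genes=frozenset(d["informative_class_genes"]),
            subgroup_genes={k: frozenset(v) for k, v in d["subgroup_genes"].items()},
            class_assignment=dict(d["class_assignment"]),
            subgroup_assignment=dict(d["subgroup_assignment"]),
            shift_signs={k: int(v) for k, v in d["shift_signs"].items()},
        )


def _assign_patients(n_visits: int, prefix: str, lo: int, hi: int,
                     rng: np.random.Generator, start_id: int) -> tuple[list[str], int]:
    """Group ``n_visits`` into patients with lo..hi visits each."""
    ids: list[str] = []
    pid = start_id
    while len(ids) < n_visits:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, n_visits - len(ids))
        ids.extend([f"{prefix}{pid:04d}"] * k)
        pid += 1
    return ids, pid


def generate(config: SimConfig) -> tuple[ExpressionBundle, GroundTruth]:
    """Draw one synthetic cohort.

    Controls are Normal(mu_g, sigma_g) per gene with mu_g, sigma_g sampled
    from the configured ranges.  Class-informative genes are shifted by
    ±delta*sigma_g in every DA3 visit (sign fixed per gene at generation);
    subgroup-informative genes are shifted only in their subgroup's
    visits.  Non-informative genes are identically distributed in all
    classes.  SLEDAI is Uniform[0,2] for DA1 and Uniform[8,20] for DA3.
    Bit-identical output is guaranteed for identical (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    n_sub = len(config.subgroup_sizes)
    n_pick = config.n_informative_class + n_sub * config.n_informative_per_subgroup
    picked = rng.choice(config.n_genes, size=n_pick, replace=False)
    class_idx = picked[: config.n_informative_class]
    sub_idx: dict[str, np.ndarray] = {}
    off = config.n_informative_class
    sub_labels = [f"S{i + 1}" for i in range(n_sub)]
    for lab in sub_labels:
        sub_idx[lab] = picked[off: off + config.n_informative_per_subgroup]
        off += config.n_informative_per_subgroup

    mu = rng.uniform(*config.control_mean_range, size=config.n_genes)
    sigma = rng.uniform(*config.control_sd_range, size=config.n_genes)
    signs = np.where(rng.random(n_pick) < 0.5, -1, 1)

    # visit layout: controls, DA1, DA3 (subgroups in blocks)
    n_total = config.n_controls + config.n_da1 + config.n_da3
    visits = [f"V{i:05d}" for i in range(1, n_total + 1)]
    classes = ([CONTROL] * config.n_controls + [DA1] * config.n_da1
               + [DA3] * config.n_da3)
    subgroup: dict[str, str] = {}
    pos = config.n_controls + config.n_da1
    for lab, size in zip(sub_labels, config.subgroup_sizes):
        for v in visits[pos: pos + size]:
            subgroup[v] = lab
        pos += size

    lo, hi = config.visits_per_patient_range
    patient_ids: list[str] = []
    pid = 1
    ctrl_ids, pid = _assign_patients(config.n_controls, "CTRL", 1, 1, rng, 1)
    patient_ids.extend(ctrl_ids)
    pid = 1
    strata = [("P", config.n_da1)] + [("P", s) for s in config.subgroup_sizes]
    for prefix, size in strata:
        ids, pid = _assign_patients(size, prefix, lo, hi, rng, pid)
        patient_ids.extend(ids)

    batches = rng.integers(1, config.batch_count + 1, size=n_total)

    X = rng.normal(loc=mu[:, None], scale=sigma[:, None],
                   size=(config.n_genes, n_total))
    cls_arr = np.asarray(classes)
    da3_cols = cls_arr == DA3
    delta = config.effect_size
    for j, g in enumerate(class_idx):
        X[g, da3_cols] += signs[j] * delta * sigma[g]
    off = config.n_informative_class
    for lab in sub_labels:
        cols = np.asarray([v in subgroup and subgroup[v] == lab for v in visits])
        for j, g in enumerate(sub_idx[lab]):
            X[g, cols] += signs[off + j] * delta * sigma[g]
        off += config.n_informative_per_subgroup

    if config.batch_effect_sd > 0 and config.batch_count > 1:
        offs = rng.normal(0.0, config.batch_effect_sd,
                          size=(config.n_genes, config.batch_count))
        for b in range(1, config.batch_count + 1):
            X[:, batches == b] += offs[:, b - 1][:, None]

    values = pd.DataFrame(X, index=genes, columns=visits)
    visit_meta = pd.DataFrame(
        {"da_class": classes, "patient_id": patient_ids,
         "batch": [f"B{b}" for b in batches]},
        index=pd.Index(visits, name="visit_id"),
    )

    # phenotypes
    pheno: dict[str, np.ndarray] = {}
    sledai = np.zeros(n_total)
    sledai[cls_arr == DA1] = rng.uniform(0.0, 2.0, size=(cls_arr == DA1).sum())
    sledai[cls_arr == DA3] = rng.uniform(8.0, 20.0, size=da3_cols.sum())
    pheno["sledai"] = np.round(sledai, 1)
    group_of = [subgroup.get(v, c) for v, c in zip(visits, classes)]
    for spec in config.phenotype_specs:
        if spec.kind == "continuous":
            base = rng.normal(spec.mean, spec.sd, size=n_total)
            shift = np.zeros(n_total)
            for i, (g, c) in enumerate(zip(group_of, classes)):
                shift[i] = spec.shifts.get(g, spec.shifts.get(c, 0.0))
                if g != c and g in spec.shifts and c in spec.shifts:
                    shift[i] = spec.shifts[g] + spec.shifts[c]
            pheno[spec.name] = base + shift
        elif spec.kind == "binary":
            rates = np.asarray([
                spec.rates.get(g, spec.rates.get(c, spec.rate))
                for g, c in zip(group_of, classes)
            ])
            pheno[spec.name] = (rng.random(n_total) < rates).astype(int)
        else:
            raise ValueError(f"unknown phenotype kind {spec.kind!r}")
    phenotypes = pd.DataFrame(pheno, index=visit_meta.index.copy())

    truth = GroundTruth(
        informative_class_genes=frozenset(genes[g] for g in class_idx),
        subgroup_genes={lab: frozenset(genes[g] for g in sub_idx[lab])
                        for lab in sub_labels},
        class_assignment=dict(zip(visits, classes)),
        subgroup_assignment=dict(subgroup),
        shift_signs={genes[g]: int(signs[j])
                     for j, g in enumerate(picked)},
    )
    bundle = ExpressionBundle(values=values, visit_meta=visit_meta,
                              phenotypes=phenotypes)
    return bundle, truth
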