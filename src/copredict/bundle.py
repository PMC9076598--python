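"""Container for an expression study: matrix, visit metadata, phenotypes.

The central in-memory object passed between pipeline stages.  Expression
values are a genes x visits :class:`pandas.DataFrame`; visit metadata and
clinical phenotypes are per-visit DataFrames indexed by visit ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CONTROL = "control"
DA1 = "DA1"
DA3 = "DA3"

#: columns of ``visit_meta`` that are structural, not phenotypes
META_COLUMNS = ("da_class", "patient_id", "batch")


@dataclass
class ExpressionBundle:
    """Expression matrix plus per-visit metadata and phenotypes.

    Parameters
    ----------
    values
        genes x visits matrix of continuous (log-scale) expression values.
    visit_meta
        One row per visit with columns ``da_class`` (control/DA1/DA3),
        ``patient_id`` and ``batch``.
    phenotypes
        One row per visit; continuous and binary clinical variables.
    """

    values: pd.DataFrame
    visit_meta: pd.DataFrame
    phenotypes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise ValueError(f"duplicate visit IDs in expression matrix: {dupes}")
        if self.values.index.duplicated().any():
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene IDs: {dupes}")
        missing = [v for v in cols if v not in self.visit_meta.index]
        if missing:
            raise ValueError(f"visits missing from metadata: {missing}")
        if "da_class" not in self.visit_meta.columns:
            raise ValueError("visit_meta must have a 'da_class' column")
        bad = set(self.visit_meta["da_class"]) - {CONTROL, DA1, DA3}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if self.values.isna().any().any():
            n = int(self.values.isna().sum().sum())
            raise ValueError(f"expression matrix contains {n} missing values")
        if len(self.phenotypes) and not self.phenotypes.index.isin(cols).all():
            extra = [v for v in self.phenotypes.index if v not in cols]
            raise ValueError(f"phenotype rows for unknown visits: {extra}")

    @property
    def visits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def classes(self) -> pd.Series:
        """Class label per visit, aligned to the matrix columns."""
        return self.visit_meta.loc[self.visits, "da_class"]

    def visits_of(self, da_class: str) -> list[str]:
        cls = self.classes()
        return list(cls.index[cls == da_class])

    def subset_visits(self, visits: list[str]) -> "ExpressionBundle":
        pheno = self.phenotypes
        if len(pheno):
            pheno = pheno.loc[[v for v in visits if v in pheno.index]]
        return ExpressionBundle(
            values=self.values[visits],
            visit_meta=self.visit_meta.loc[visits],
            phenotypes=pheno,
        )
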