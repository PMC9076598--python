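"""Probe collapsing, log transform and control-based discretization.

The discretizer projects every disease visit onto the healthy-control
distribution of each gene: values at or below mu - 2*sigma are coded Low
(1), values at or above mu + 2*sigma are coded High (3), everything in
between is Medium (2).  mu and sigma are the control mean and sample
standard deviation of that gene, so the coding expresses "how far outside
the healthy range" an expression value lies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import CONTROL, ExpressionBundle

log = logging.getLogger(__name__)

LOW, MEDIUM, HIGH = 1, 2, 3


def collapse_probes(probe_matrix: pd.DataFrame,
                    probe_map: dict[str, str]) -> pd.DataFrame:
    """Average probe rows that map to the same gene.

    Unmapped probes are dropped (count logged).  Gene order in the result
    is lexicographic, making the operation deterministic.
    """
    if not probe_map:
        raise ValueError("empty probe-to-gene mapping")
    mapped = [p for p in probe_matrix.index if p in probe_map]
    n_dropped = len(probe_matrix) - len(mapped)
    if n_dropped:
        log.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    if not mapped:
        raise ValueError("no probe in the matrix has a gene mapping")
    sub = probe_matrix.loc[mapped]
    genes = pd.Index([probe_map[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes).mean()
    return collapsed.sort_index()


def log_transform(matrix: pd.DataFrame, base: float = 2.0) -> pd.DataFrame:
    """Element-wise logarithm (base 2 by default); rejects non-positive cells."""
    vals = matrix.to_numpy(dtype=float)
    bad = np.argwhere(~(vals > 0))
    if len(bad):
        cells = [(matrix.index[i], matrix.columns[j]) for i, j in bad[:10]]
        raise ValueError(
            f"log_transform requires strictly positive values; "
            f"{len(bad)} offending cells, first: {cells}")
    return pd.DataFrame(np.log(vals) / np.log(base),
                        index=matrix.index, columns=matrix.columns)


@dataclass
class DiscretizationModel:
    """Per-gene control mean and sample SD (ddof=1) defining the 1/2/3 coding."""

    mu: pd.Series
    sigma: pd.Series

    def __post_init__(self) -> None:
        if not self.mu.index.equals(self.sigma.index):
            raise ValueError("mu and sigma must share a gene index")
        if (self.sigma < 0).any():
            raise ValueError("sigma must be nonnegative")

    @property
    def degenerate_genes(self) -> list[str]:
        """Genes whose control expression was constant (sigma == 0)."""
        return list(self.sigma.index[self.sigma == 0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mu": self.mu, "sigma": self.sigma})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DiscretizationModel":
        return cls(mu=df["mu"].astype(float), sigma=df["sigma"].astype(float))


def fit_discretizer(bundle: ExpressionBundle) -> DiscretizationModel:
    """Fit mu_g, sigma_g on control visits only (sample SD, n-1)."""
    controls = bundle.visits_of(CONTROL)
    if len(controls) < 2:
        raise ValueError(
            f"need >= 2 control visits to fit a discretizer, got {len(controls)}")
    ctrl = bundle.values[controls]
    mu = ctrl.mean(axis=1)
    sigma = ctrl.std(axis=1, ddof=1)
    model = DiscretizationModel(mu=mu, sigma=sigma)
    if model.degenerate_genes:
        log.warning("fit_discretizer: %d genes with constant control expression",
                    len(model.degenerate_genes))
    return model


def discretize(matrix: pd.DataFrame,
               model: DiscretizationModel) -> pd.DataFrame:
    """Code each value against the control frame: 1=Low, 2=Medium, 3=High.

    Low wins at exact equality with mu - 2*sigma.  Genes with sigma == 0
    code 2 only at exactly mu, otherwise 1/3 by sign of the deviation.
    """
    missing = [g for g in matrix.index if g not in model.mu.index]
    if missing:
        raise KeyError(f"genes missing from discretization model: {missing[:10]}")
    mu = model.mu.loc[matrix.index].to_numpy()[:, None]
    sigma = model.sigma.loc[matrix.index].to_numpy()[:, None]
    x = matrix.to_numpy(dtype=float)
    codes = np.full(x.shape, MEDIUM, dtype=np.int8)
    codes[x >= mu + 2 * sigma] = HIGH
    codes[x <= mu - 2 * sigma] = LOW
    # sigma == 0: both bounds collapse onto mu; recode by sign of deviation
    zero = (sigma == 0).ravel()
    if zero.any():
        sub = x[zero] - mu[zero]
        c = np.full(sub.shape, MEDIUM, dtype=np.int8)
        c[sub > 0] = HIGH
        c[sub < 0] = LOW
        codes[zero] = c
    return pd.DataFrame(codes, index=matrix.index, columns=matrix.columns)


def center_batches(matrix: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Per-batch mean-centering stub: subtract each batch's per-gene mean and
    add back the overall per-gene mean.  A deliberately simple correction;
    surrogate-variable style adjustment is out of scope."""
    batch = batch.loc[matrix.columns]
    out = matrix.copy()
    grand = matrix.mean(axis=1)
    for b in batch.unique():
        cols = batch.index[batch == b]
        out[cols] = matrix[cols].sub(matrix[cols].mean(axis=1), axis=0).add(grand, axis=0)
    return out
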