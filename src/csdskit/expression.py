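"""Microarray-style expression preprocessing and differential testing.

The pipeline starts at a gene x sample intensity matrix (median signal,
linear scale) and applies, in order: log2 transform, batch-effect
correction by per-gene batch-mean centering, quantile normalization, and
housekeeping-relative expression (subtract the Gapdh log2 value per
sample, then center each gene on the control-group mean so control fold
change is 1).  Per-gene differential calls are unpaired pooled-variance
t-tests at alpha = 0.05, uncorrected by default (Benjamini-Hochberg
optional).  A scale tag on the matrix enforces the stage order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stats import ttest_unpaired

__all__ = [
    "ExpressionMatrix",
    "DifferentialResult",
    "log2_transform",
    "batch_correct",
    "quantile_normalize",
    "relative_expression",
    "differential_tests",
    "zscore_matrix",
]

# allowed scale progression; each op names the stages it accepts
_STAGES = ("linear", "log2", "log2_batch", "log2_qnorm", "relative")


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix with sample metadata and a scale tag.

    ``values``: DataFrame indexed by gene symbol, one column per sample.
    ``sample_meta``: DataFrame indexed by sample with ``group`` and
    ``batch`` columns.  ``scale`` tracks the last transform applied so
    out-of-order pipeline calls fail loudly.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self):
        if self.scale not in _STAGES:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        missing = [s for s in self.values.columns
                   if s not in self.sample_meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def _require(self, *scales: str, op: str = "") -> None:
        if self.scale not in scales:
            raise ValueError(
                f"{op} expects scale in {scales}, got {self.scale!r}"
            )


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2 of a linear-scale intensity matrix."""
    m._require("linear", op="log2_transform")
    bad = m.values <= 0
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        sample = bad.loc[gene].idxmax()
        raise ValueError(
            f"non-positive intensity at gene {gene!r}, sample {sample!r}"
        )
    return replace(m, values=np.log2(m.values), scale="log2")


def batch_correct(m: ExpressionMatrix, batches=None) -> ExpressionMatrix:
    """One-way mean centering of batch effects on the log2 scale.

    Per gene, each batch's mean is subtracted and the grand mean added
    back; experimental-group structure is ignored during centering.  A
    single-sample batch is allowed (it is centered to the grand mean)
    with a warning.
    """
    m._require("log2", "log2_batch", op="batch_correct")  # idempotent
    if batches is None:
        batches = m.sample_meta["batch"]
    batches = pd.Series(batches, index=m.values.columns)
    if batches.isna().any():
        raise ValueError("every sample needs a batch label")
    counts = batches.value_counts()
    singletons = counts[counts == 1].index.tolist()
    if singletons:
        warnings.warn(f"batches with a single sample: {singletons}")
    v = m.values
    grand = v.mean(axis=1)
    corrected = v.copy()
    for batch in counts.index:
        cols = v.columns[(batches == batch).to_numpy()]
        batch_mean = v[cols].mean(axis=1)
        corrected[cols] = v[cols].sub(batch_mean, axis=0).add(grand, axis=0)
    return replace(m, values=corrected, scale="log2_batch")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standard quantile normalization across samples.

    Each column is sorted, values are averaged across columns at each
    rank to build the reference distribution, and every value is mapped
    back by its within-column rank; ties receive the mean of their tied
    ranks' reference values.
    """
    m._require("log2", "log2_batch", op="quantile_normalize")
    v = m.values.to_numpy(dtype=float)
    order = np.sort(v, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        col = v[:, j]
        idx = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[idx] = reference
        # tied input values share the mean of their ranks' reference values
        out[:, j] = (
            pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
            .to_numpy()
        )
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return replace(m, values=values, scale="log2_qnorm")


def relative_expression(
    m: ExpressionMatrix,
    housekeeping: str = "Gapdh",
    control_group: str = "control",
) -> ExpressionMatrix:
    """Housekeeping-relative, control-normalized expression (log2 scale).

    Per sample the housekeeping gene's log2 value is subtracted; per
    gene the control-group mean is then subtracted, so the control mean
    is 0 on the log2 scale (fold change 1 on the linear scale).
    """
    m._require("log2", "log2_batch", "log2_qnorm", op="relative_expression")
    if housekeeping not in m.values.index:
        raise ValueError(f"housekeeping gene {housekeeping!r} not in matrix")
    groups = m.sample_meta.loc[m.values.columns, "group"]
    control_cols = m.values.columns[groups == control_group]
    if not len(control_cols):
        raise ValueError(f"no samples in control group {control_group!r}")
    v = m.values.sub(m.values.loc[housekeeping], axis=1)
    v = v.sub(v[control_cols].mean(axis=1), axis=0)
    return replace(m, values=v, scale="relative")


@dataclass
class DifferentialResult:
    """Per-gene unpaired t-test results between two sample groups."""

    table: pd.DataFrame  # gene-indexed: log2_fc, fold_change, t, p, significant
    alpha: float
    n_significant: int
    groups: tuple[str, str]
    bh_adjusted: bool = False


def differential_tests(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    bh: bool = False,
) -> DifferentialResult:
    """Per-gene unpaired two-sample t-tests (group_b vs group_a).

    Fold changes are reported from the log2 difference of group means
    (group_b minus group_a; on relative-expression input with group_a
    the control this is the control-normalized fold change).  Flags are
    p < alpha, uncorrected unless ``bh`` requests Benjamini-Hochberg.
    """
    groups = m.sample_meta.loc[m.values.columns, "group"]
    cols_a = m.values.columns[groups == group_a]
    cols_b = m.values.columns[groups == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    m._require("log2", "log2_batch", "log2_qnorm", "relative",
               op="differential_tests")

    rows = []
    for gene in m.values.index:
        a = m.values.loc[gene, cols_a].to_numpy(dtype=float)
        b = m.values.loc[gene, cols_b].to_numpy(dtype=float)
        res = ttest_unpaired(b, a)
        log2_fc = float(b.mean() - a.mean())
        rows.append((gene, log2_fc, 2.0 ** log2_fc, res.t, res.p))
    table = pd.DataFrame(
        rows, columns=["gene", "log2_fc", "fold_change", "t", "p"]
    ).set_index("gene")
    if bh:
        table["p_adjusted"] = _benjamini_hochberg(table["p"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return DifferentialResult(
        table=table,
        alpha=alpha,
        n_significant=int(table["significant"].sum()),
        groups=(group_a, group_b),
        bh_adjusted=bh,
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def zscore_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene Z-scores across samples (heatmap input).

    Genes with zero standard deviation map to all-zero rows with a
    warning.
    """
    if m.values.shape[1] < 2:
        raise ValueError("need >= 2 samples for Z-scores")
    v = m.values
    mu = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"constant genes mapped to zero rows: {list(v.index[flat])}"
        )
        sd = sd.mask(flat, 1.0)
    z = v.sub(mu, axis=0).div(sd, axis=0)
    z.loc[flat] = 0.0
    return z
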