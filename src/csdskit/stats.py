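"""Shared inferential statistics for the pipeline.

Every downstream module (behavioral scoring, resilience classification,
expression differential tests) calls through this module, so the unpaired
t-test, the factorial ANOVA and Fisher's exact test are audited in a single
place.  The test statistics are computed here from first principles; only
the reference distributions (Student t, F, hypergeometric) are delegated to
scipy.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaTerm",
    "AnovaResult",
    "FisherResult",
    "ttest_unpaired",
    "anova_factorial",
    "fisher_exact_2x2",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float

    def __iter__(self):
        return iter((self.t, self.df, self.p))


@dataclass(frozen=True)
class AnovaTerm:
    """One row of a factorial ANOVA table: F(df1, df2) and its p-value."""

    term: str
    ss: float
    df1: int
    df2: int
    F: float
    p: float


@dataclass
class AnovaResult:
    """Factorial ANOVA table with Type II sums of squares."""

    terms: dict[str, AnovaTerm]
    ss_type: str = "II"
    residual_ss: float = float("nan")
    residual_df: int = 0

    def __getitem__(self, term: str) -> AnovaTerm:
        return self.terms[term]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t.term, "ss": t.ss, "df1": t.df1, "df2": t.df2,
             "F": t.F, "p": t.p}
            for t in self.terms.values()
        ]
        return pd.DataFrame(rows).set_index("term")


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p: float

    def __iter__(self):
        return iter((self.odds_ratio, self.p))


def ttest_unpaired(a, b) -> TTestResult:
    """Two-sided unpaired Student t-test with pooled variance.

    df = len(a) + len(b) - 2.  A degenerate comparison (zero pooled
    variance) returns t = 0, p = 1 when the means agree and t = +/-inf,
    p = 0 with a warning when they do not.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = na + nb - 2
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0)
        warnings.warn("zero pooled variance with unequal means: |t| -> inf")
        return TTestResult(math.copysign(math.inf, diff), df, 0.0)
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def _sum_contrast(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    levels = sorted(pd.unique(labels).tolist())
    k = len(levels)
    idx = {lv: i for i, lv in enumerate(levels)}
    cols = np.zeros((labels.size, k - 1))
    for row, lab in enumerate(labels):
        i = idx[lab]
        if i < k - 1:
            cols[row, i] = 1.0
        else:
            cols[row, :] = -1.0
    return cols, levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova_factorial(values, factors, max_order: int | None = None) -> AnovaResult:
    """Factorial ANOVA with Type II sums of squares.

    Parameters
    ----------
    values : 1-d array of responses.
    factors : mapping name -> label sequence (or a DataFrame of labels),
        one label per observation.  Two- and three-way designs with
        unbalanced cells (n = 7-10 per cell is typical here) are the
        intended use.
    max_order : highest interaction order fitted; defaults to the number
        of factors (full factorial).

    The Type II sum of squares for a term compares the model containing
    every term that does not include it against that model plus the term,
    with F tested against the full-model residual.
    """
    y = np.asarray(values, dtype=float)
    if isinstance(factors, pd.DataFrame):
        factors = {c: factors[c].to_numpy() for c in factors.columns}
    names = list(factors)
    coded = {}
    for name in names:
        labs = np.asarray(factors[name])
        if labs.size != y.size:
            raise ValueError(f"factor {name!r} length mismatch")
        cols, levels = _sum_contrast(labs)
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
        coded[name] = cols

    if max_order is None:
        max_order = len(names)
    terms: list[tuple[str, ...]] = []
    for order in range(1, max_order + 1):
        terms.extend(itertools.combinations(names, order))

    # every requested interaction needs at least one observation per cell
    cell_labels = pd.DataFrame({n: np.asarray(factors[n]) for n in names})
    n_levels = {n: len(pd.unique(cell_labels[n])) for n in names}
    for term in terms:
        observed = cell_labels.groupby(list(term)).size()
        expected = int(np.prod([n_levels[n] for n in term]))
        if len(observed) < expected:
            raise ValueError(f"empty cell for term {':'.join(term)}")

    def term_cols(term: tuple[str, ...]) -> np.ndarray:
        block = coded[term[0]]
        for name in term[1:]:
            nxt = coded[name]
            block = np.einsum("ij,ik->ijk", block, nxt).reshape(y.size, -1)
        return block

    def design(term_subset) -> np.ndarray:
        blocks = [np.ones((y.size, 1))]
        blocks.extend(term_cols(t) for t in term_subset)
        return np.hstack(blocks)

    X_full = design(terms)
    rss_full = _rss(X_full, y)
    df_resid = y.size - int(np.linalg.matrix_rank(X_full))
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")

    table: dict[str, AnovaTerm] = {}
    for term in terms:
        others = [t for t in terms if not set(term) <= set(t)]
        rss_reduced = _rss(design(others), y)
        rss_with = _rss(design(others + [term]), y)
        ss = max(rss_reduced - rss_with, 0.0)
        df1 = int(np.prod([coded[n].shape[1] for n in term]))
        ms_resid = rss_full / df_resid
        if ms_resid > 0:
            F = (ss / df1) / ms_resid
            p = float(sps.f.sf(F, df1, df_resid))
        elif ss > 0:  # perfect fit with a real effect
            F, p = math.inf, 0.0
        else:  # e.g. all observations equal
            F, p = 0.0, 1.0
        key = ":".join(term)
        table[key] = AnovaTerm(key, ss, df1, df_resid, float(F), p)

    return AnovaResult(terms=table, residual_ss=rss_full, residual_df=df_resid)


def fisher_exact_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test for a 2x2 contingency table.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric point probabilities no larger than the observed
    table's (with a 1 + 1e-7 relative guard against ties lost to
    floating point).  The odds ratio is the sample ratio ad/bc, NaN when
    undefined.  A zero margin makes every table with those margins
    identical, so p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n_tot = r1 + r2
    if n_tot == 0:
        raise ValueError("empty table")

    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan

    if 0 in (r1, r2, c1, b + d):
        return FisherResult(odds, 1.0)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    denom = math.comb(n_tot, c1)
    pmf = {
        x: math.comb(r1, x) * math.comb(r2, c1 - x) / denom
        for x in range(lo, hi + 1)
    }
    p_obs = pmf[a]
    p = sum(v for v in pmf.values() if v <= p_obs * (1.0 + 1e-7))
    return FisherResult(odds, float(min(p, 1.0)))
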