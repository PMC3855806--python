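"""Differential expression and enrichment statistics for biomarker triage.

Fold change is the ratio of aggregate case to aggregate control expression
per gene; genes pass with fold change ≥ 1.5 (or ≤ 1/1.5) and a paired-t
p-value below the cutoff. Set overlaps are scored with the hypergeometric
distribution — both the point mass and the upper tail are exposed, since
surveys of ranked candidate lists conventionally report either.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ExpressionMatrix",
    "EnrichmentQuery",
    "fold_change",
    "paired_ttest",
    "select_deg",
    "hypergeom_pmf",
    "hypergeom_tail",
    "intersect_candidates",
]


@dataclass
class ExpressionMatrix:
    """Paired case/control expression, linear scale, positive values."""

    gene_ids: list[str]
    case: np.ndarray  # genes × m
    control: np.ndarray  # genes × m

    def __post_init__(self) -> None:
        self.case = np.asarray(self.case, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.case.shape != self.control.shape:
            raise ValueError("case and control must have identical shapes")
        if self.case.ndim != 2:
            raise ValueError("expression matrices must be 2-D (genes × pairs)")
        if len(self.gene_ids) != self.case.shape[0]:
            raise ValueError("gene_ids length must match the matrices")
        if np.any(self.case <= 0) or np.any(self.control <= 0):
            raise ValueError("expression values must be positive")

    @property
    def m(self) -> int:
        return self.case.shape[1]

    def to_frame(self) -> pd.DataFrame:
        m = self.m
        cols = [f"case_{j+1}" for j in range(m)] + [f"control_{j+1}" for j in range(m)]
        return pd.DataFrame(
            np.hstack([self.case, self.control]),
            index=pd.Index(self.gene_ids, name="gene"),
            columns=cols,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        case_cols = [c for c in df.columns if c.startswith("case_")]
        ctrl_cols = [c for c in df.columns if c.startswith("control_")]
        if len(case_cols) != len(ctrl_cols) or not case_cols:
            raise ValueError("expected equal numbers of case_*/control_* columns")
        return cls(
            gene_ids=[str(g) for g in df.index],
            case=df[case_cols].to_numpy(dtype=float),
            control=df[ctrl_cols].to_numpy(dtype=float),
        )


def fold_change(expr: ExpressionMatrix, method: str = "ratio_of_sums") -> np.ndarray:
    """Per-gene case/control fold change.

    ``ratio_of_sums`` (default) divides total case expression by total
    control expression; ``mean_of_ratios`` averages per-pair ratios. Values
    above 1 indicate up-regulation in cases.
    """
    if method == "ratio_of_sums":
        denom = expr.control.sum(axis=1)
        if np.any(denom <= 0):
            raise ValueError("non-positive control sum")
        return expr.case.sum(axis=1) / denom
    if method == "mean_of_ratios":
        return (expr.case / expr.control).mean(axis=1)
    raise ValueError(f"unknown fold-change method {method!r}")


def paired_ttest(expr: ExpressionMatrix) -> np.ndarray:
    """Two-sided paired t-test p-values on case − control differences.

    Degenerate rows: all differences zero → p = 1; identical nonzero
    differences (zero variance but a definite shift) → the smallest
    positive float, never exactly 0.
    """
    if expr.m < 2:
        raise ValueError("paired t-test requires at least two pairs")
    diff = expr.case - expr.control
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_rel(expr.case, expr.control, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = diff.std(axis=1) == 0
    all_zero = zero_var & np.all(diff == 0, axis=1)
    shifted = zero_var & ~all_zero
    p[all_zero] = 1.0
    p[shifted] = np.finfo(float).tiny
    return p


def select_deg(
    fc: np.ndarray,
    pvals: np.ndarray,
    gene_ids: Sequence[str],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> list[str]:
    """Differentially expressed genes: |regulation| at or beyond the fold
    threshold (inclusive, 1/threshold for down) and p below the cutoff."""
    fc = np.asarray(fc, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    if not (len(fc) == len(pvals) == len(gene_ids)):
        raise ValueError("fc, pvals and gene_ids must be aligned")
    keep = ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)) & (pvals < p_threshold)
    return [g for g, k in zip(gene_ids, keep) if k]


@dataclass(frozen=True)
class EnrichmentQuery:
    """Overlap test: s marked items among n draws from N containing S marked."""

    N: int
    S: int
    n: int
    s: int

    def __post_init__(self) -> None:
        if min(self.N, self.S, self.n, self.s) < 0:
            raise ValueError("all counts must be non-negative")
        if self.S > self.N or self.n > self.N:
            raise ValueError("S and n cannot exceed N")
        if self.s > min(self.S, self.n):
            raise ValueError("s cannot exceed min(S, n)")
        if self.s < max(0, self.n - (self.N - self.S)):
            raise ValueError("s below the feasible minimum for this query")


def _log_comb(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pmf(q: EnrichmentQuery) -> float:
    """Point probability C(S,s)·C(N−S,n−s)/C(N,n) via log-gamma."""
    logp = (
        _log_comb(q.S, q.s)
        + _log_comb(q.N - q.S, q.n - q.s)
        - _log_comb(q.N, q.n)
    )
    return float(np.exp(logp))


def hypergeom_tail(q: EnrichmentQuery) -> float:
    """Upper tail P(X ≥ s), the sum of point masses from s upward."""
    hi = min(q.S, q.n)
    total = 0.0
    for k in range(q.s, hi + 1):
        total += hypergeom_pmf(EnrichmentQuery(q.N, q.S, q.n, k))
    return min(total, 1.0)


def intersect_candidates(
    deg_ids: Sequence[str],
    blood_secretory_ids: Sequence[str],
    saliva_predicted_ids: Sequence[str],
    ranking: dict[str, int] | None = None,
) -> list[str]:
    """Candidate biomarkers: genes that are differentially expressed, blood
    secretory and predicted saliva-movable; ordered by manifold rank when
    provided, else by id."""
    common = set(deg_ids) & set(blood_secretory_ids) & set(saliva_predicted_ids)
    if ranking:
        return sorted(common, key=lambda g: (ranking.get(g, float("inf")), g))
    return sorted(common)
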