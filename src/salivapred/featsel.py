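"""Two-stage feature selection: permutation-test q-value filter, then SVM-RFE.

Stage one scores every feature element by the absolute Welch t statistic
between the two classes, obtains a permutation p-value by label shuffling
(add-one rule, so p is never exactly zero), converts to Storey q-values and
keeps elements with q below the cutoff. Stage two ranks the survivors by
recursive feature elimination under a linear soft-margin SVM — collapsing
near-duplicate features (|r| > 0.98) into groups so redundant elements rise
or fall together — and returns the smallest nested subset whose
cross-validated recall and precision match the full survivor set within a
tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import classify

__all__ = [
    "SelectionResult",
    "permutation_pvalues",
    "qvalues",
    "svm_rfe",
    "select",
]


@dataclass
class SelectionResult:
    """Per-feature selection diagnostics plus the global outcome."""

    feature_names: list[str]
    statistic: np.ndarray
    pvalue: np.ndarray
    qvalue: np.ndarray
    rfe_rank: np.ndarray  # 1 = eliminated first; 0 = removed at stage 1
    selected: np.ndarray  # boolean
    pi0: float
    q_cutoff: float

    @property
    def selected_names(self) -> list[str]:
        return [n for n, s in zip(self.feature_names, self.selected) if s]

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "statistic": self.statistic,
                "pvalue": self.pvalue,
                "qvalue": self.qvalue,
                "rfe_rank": self.rfe_rank,
                "selected": self.selected.astype(int),
            }
        )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    return y


def _abs_welch_t(sum1, sumsq1, n1, sum0, sumsq0, n0) -> np.ndarray:
    """Vectorized |Welch t| from per-class sums and sums of squares."""
    m1 = sum1 / n1
    m0 = sum0 / n0
    v1 = np.maximum(sumsq1 / n1 - m1**2, 0.0) * (n1 / (n1 - 1))
    v0 = np.maximum(sumsq0 / n0 - m0**2, 0.0) * (n0 / (n0 - 1))
    se = np.sqrt(v1 / n1 + v0 / n0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(m1 - m0) / se
    t[~np.isfinite(t)] = 0.0
    return t


def permutation_pvalues(
    X, y, n_perm: int = 10000, seed: int | None = 0, batch: int = 2000
) -> np.ndarray:
    """Per-feature permutation p-values for the |Welch t| class statistic.

    Labels are shuffled jointly for all features in each permutation;
    p = (1 + #{permuted |t| ≥ observed}) / (1 + n_perm). Features constant
    across all samples get p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xm, _ = _as_matrix(X)
    y = _check_labels(y)
    pos = y == np.max(y)
    n, m = Xm.shape
    n1 = int(pos.sum())
    n0 = n - n1
    if min(n0, n1) < 2:
        raise ValueError("each class needs at least two samples")

    total = Xm.sum(axis=0)
    total_sq = (Xm**2).sum(axis=0)
    Xsq = Xm**2

    mask = pos.astype(float)
    obs = _abs_welch_t(mask @ Xm, mask @ Xsq, n1, total - mask @ Xm,
                       total_sq - mask @ Xsq, n0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(m, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        # b random permutations of the label mask, as rows
        perm = np.argsort(rng.random((b, n)), axis=1)[:, :n1]
        masks = np.zeros((b, n))
        np.put_along_axis(masks, perm, 1.0, axis=1)
        s1 = masks @ Xm
        sq1 = masks @ Xsq
        t = _abs_welch_t(s1, sq1, n1, total - s1, total_sq - sq1, n0)
        exceed += (t >= obs[None, :] - 1e-12).sum(axis=0)
        done += b

    p = (1.0 + exceed) / (1.0 + n_perm)
    constant = Xm.std(axis=0) == 0
    p[constant] = 1.0
    return p


def qvalues(pvals, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with fixed λ.

    π̂0 = min(1, #{p > λ} / ((1−λ)·m)); q(p_(i)) = min_{j≥i} π̂0·m·p_(j)/j
    over ascending p, capped at 1, mapped back to input order. π̂0 is
    floored at 1/m so q-values stay strictly positive when every p ≤ λ.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    pi0 = min(1.0, max(np.sum(p > lam) / ((1.0 - lam) * m), 1.0 / m))
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _correlation_groups(Xm: np.ndarray, threshold: float) -> list[list[int]]:
    """Union-find grouping of features with |pearson r| > threshold."""
    m = Xm.shape[1]
    sd = Xm.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(Xm, rowvar=False)
    r = np.nan_to_num(np.atleast_2d(r), nan=0.0)

    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ii, jj = np.nonzero(np.triu(np.abs(r) > threshold, k=1))
    for i, j in zip(ii, jj):
        if sd[i] == 0 or sd[j] == 0:
            continue
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    return [groups[k] for k in sorted(groups)]


def svm_rfe(
    X,
    y,
    step_fraction: float = 0.1,
    C: float = 1.0,
    corr_threshold: float = 0.98,
    seed: int | None = 0,
) -> np.ndarray:
    """Recursive feature elimination ranking under a linear SVM.

    Features are first collapsed into near-duplicate groups (|r| >
    ``corr_threshold``); groups are eliminated as units by the squared
    weight of their representative, ⌈step_fraction × remaining⌉ (≥1) per
    round. Returns per-feature elimination ranks, 1 = eliminated first;
    members of a group share a rank. Survival to the end gives the highest
    rank.
    """
    Xm, _ = _as_matrix(X)
    y = _check_labels(y)
    if Xm.shape[1] < 2:
        raise ValueError("svm_rfe requires at least two features")
    if not 0 < step_fraction <= 1:
        raise ValueError("step_fraction must be in (0, 1]")

    groups = _correlation_groups(Xm, corr_threshold)
    reps = [g[0] for g in groups]
    active = list(range(len(groups)))
    ranks = np.zeros(Xm.shape[1], dtype=int)
    next_rank = 1

    mu = Xm.mean(axis=0)
    sd = Xm.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xm - mu) / sd

    while active:
        if len(active) == 1:
            for f in groups[active[0]]:
                ranks[f] = next_rank
            break
        cols = [reps[g] for g in active]
        model = SVC(kernel="linear", C=C)
        model.fit(Z[:, cols], y)
        w2 = np.asarray(model.coef_).ravel() ** 2
        k = min(max(1, math.ceil(step_fraction * len(active))), len(active) - 1)
        drop_order = np.argsort(w2, kind="stable")[:k]
        for pos in drop_order:  # ascending weight: weakest first
            g = active[pos]
            for f in groups[g]:
                ranks[f] = next_rank
            next_rank += 1
        active = [g for i, g in enumerate(active) if i not in set(drop_order)]
    return ranks


def select(
    X,
    y,
    q_cutoff: float = 0.005,
    perf_tolerance: float = 0.01,
    cv_folds: int = 10,
    n_perm: int = 10000,
    step_fraction: float = 0.1,
    seed: int = 0,
) -> SelectionResult:
    """Run the full two-stage selection and return per-feature diagnostics.

    Stage 1 keeps features with q < ``q_cutoff``; stage 2 ranks survivors by
    ``svm_rfe`` and picks the smallest nested subset (by elimination order)
    whose ``cv_folds``-fold CV recall and precision are each within
    ``perf_tolerance`` of the full survivor set.
    """
    Xm, names = _as_matrix(X)
    y = _check_labels(y)

    pvals = permutation_pvalues(Xm, y, n_perm=n_perm, seed=seed)
    qvals = qvalues(pvals)

    # observed statistic, for the report
    pos = y == np.max(y)
    n1, n0 = int(pos.sum()), int((~pos).sum())
    stat = _abs_welch_t(
        Xm[pos].sum(axis=0), (Xm[pos] ** 2).sum(axis=0), n1,
        Xm[~pos].sum(axis=0), (Xm[~pos] ** 2).sum(axis=0), n0,
    )

    pi0 = min(1.0, max(np.sum(pvals > 0.5) / (0.5 * len(pvals)), 1.0 / len(pvals)))
    survivors = np.flatnonzero(qvals < q_cutoff)
    if survivors.size == 0:
        raise ValueError(
            "q-value filter removed every feature; consider a larger q_cutoff"
        )

    rfe_rank = np.zeros(Xm.shape[1], dtype=int)
    selected = np.zeros(Xm.shape[1], dtype=bool)
    if survivors.size == 1:
        rfe_rank[survivors] = 1
        selected[survivors] = True
    else:
        sub_ranks = svm_rfe(
            Xm[:, survivors], y, step_fraction=step_fraction, seed=seed
        )
        rfe_rank[survivors] = sub_ranks

        def cv_perf(cols: np.ndarray) -> tuple[float, float]:
            metrics = classify.cross_validate(
                Xm[:, cols], y, folds=cv_folds, repeats=1, seed=seed
            )
            return metrics.recall, metrics.precision

        base_recall, base_precision = cv_perf(survivors)
        thresholds = np.unique(sub_ranks)[::-1]  # highest rank = last eliminated
        chosen_cols = survivors
        for t in thresholds:  # smallest nested subset first
            cols = survivors[sub_ranks >= t]
            r, p = cv_perf(cols)
            if r >= base_recall - perf_tolerance and p >= base_precision - perf_tolerance:
                chosen_cols = cols
                break
        selected[chosen_cols] = True

    return SelectionResult(
        feature_names=names,
        statistic=stat,
        pvalue=pvals,
        qvalue=qvals,
        rfe_rank=rfe_rank,
        selected=selected,
        pi0=pi0,
        q_cutoff=q_cutoff,
    )
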