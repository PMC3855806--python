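"""Manifold ranking of background proteins against a positive set.

A Gaussian-kernel similarity graph connects all proteins; relevance
propagates from the positive ("true") samples along edges until the
iteration f ← αSf + (1−α)y converges, with S the symmetrically normalized
affinity matrix. Background proteins are then ordered by their accumulated
relevance score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .biomarker import EnrichmentQuery, hypergeom_pmf

__all__ = ["RankingConfig", "RankingResult", "build_affinity", "manifold_rank", "evaluate_ranking"]


@dataclass
class RankingConfig:
    alpha: float = 0.99
    sigma: float | str = "auto"
    k_neighbors: int | str = "dense"
    tolerance: float = 1e-9
    max_iter: int = 10000
    dense_limit: int = 2000  # auto-switch to kNN graphs above this size

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.sigma != "auto" and not (isinstance(self.sigma, (int, float)) and self.sigma > 0):
            raise ValueError("sigma must be positive or 'auto'")


def build_affinity(X, config: RankingConfig | None = None) -> np.ndarray:
    """Gaussian affinity matrix W_ij = exp(−‖x_i−x_j‖²/(2σ²)), zero diagonal.

    σ = "auto" uses the median pairwise Euclidean distance. With a finite
    ``k_neighbors`` each node keeps its k largest weights and the matrix is
    symmetrized by the elementwise maximum.
    """
    config = config or RankingConfig()
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    n = Xm.shape[0]
    if n < 2:
        raise ValueError("affinity graph needs at least two nodes")
    d = pdist(Xm)
    if config.sigma == "auto":
        sigma = float(np.median(d))
        if sigma == 0:
            raise ValueError(
                "median pairwise distance is 0 (identical rows); pass an explicit sigma"
            )
    else:
        sigma = float(config.sigma)
    W = squareform(np.exp(-(d**2) / (2.0 * sigma**2)))
    np.fill_diagonal(W, 0.0)

    k = config.k_neighbors
    if k == "dense":
        k = None if n <= config.dense_limit else 20
    if k is not None:
        k = int(k)
        if k < 1:
            raise ValueError("k_neighbors must be >= 1")
        keep = np.zeros_like(W, dtype=bool)
        nbr = np.argsort(-W, axis=1)[:, :k]
        rows = np.repeat(np.arange(n), k)
        keep[rows, nbr.ravel()] = True
        W = np.where(keep | keep.T, W, 0.0)
    return W


@dataclass
class RankingResult:
    ids: list[str]
    scores: np.ndarray
    background_order: list[str]  # descending score, ties by id
    n_iter: int
    converged: bool

    def score_of(self, node_id: str) -> float:
        return float(self.scores[self.ids.index(node_id)])

    def to_frame(self) -> pd.DataFrame:
        ranks = {nid: i + 1 for i, nid in enumerate(self.background_order)}
        rows = [
            {"id": nid, "score": self.score_of(nid), "rank": ranks[nid]}
            for nid in self.background_order
        ]
        return pd.DataFrame(rows)


def manifold_rank(
    W: np.ndarray,
    positive_ids: Sequence[str],
    ids: Sequence[str],
    config: RankingConfig | None = None,
) -> RankingResult:
    """Propagate relevance from positives over the graph and rank the rest.

    Iterates f ← αSf + (1−α)y from f = y, with S = D^{−1/2} W D^{−1/2}
    (rows of isolated nodes stay zero) and y the positive-set indicator,
    until the max absolute update falls below the tolerance; the fixed point
    equals (1−α)(I − αS)^{−1} y. Positives stay in the graph but are
    excluded from the reported background ordering.
    """
    config = config or RankingConfig()
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if np.any(W < 0):
        raise ValueError("W must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have a zero diagonal")
    ids = [str(i) for i in ids]
    if len(ids) != W.shape[0]:
        raise ValueError("ids length must match W")
    pos = set(map(str, positive_ids))
    if not pos:
        raise ValueError("positive set must be non-empty")
    unknown = pos - set(ids)
    if unknown:
        raise ValueError(f"positive ids not in graph: {sorted(unknown)}")

    deg = W.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    S = W * inv_sqrt[:, None] * inv_sqrt[None, :]

    y = np.array([1.0 if i in pos else 0.0 for i in ids])
    alpha = config.alpha
    f = y.copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        f_new = alpha * (S @ f) + (1.0 - alpha) * y
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < config.tolerance:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"manifold ranking did not converge in {config.max_iter} iterations "
            f"(residual {delta:.3e})"
        )

    background = [i for i in ids if i not in pos]
    idx = {i: k for k, i in enumerate(ids)}
    order = sorted(background, key=lambda i: (-f[idx[i]], i))
    return RankingResult(ids=ids, scores=f, background_order=order,
                         n_iter=n_iter, converged=converged)


def evaluate_ranking(
    result: RankingResult,
    known_ids: Sequence[str],
    top_n: int,
    population_N: int,
) -> tuple[int, float]:
    """Overlap of a known set with the top-n ranked background proteins,
    plus the hypergeometric point probability of that overlap."""
    if top_n > len(result.background_order):
        raise ValueError("top_n exceeds the number of ranked proteins")
    known = set(map(str, known_ids))
    top = set(result.background_order[:top_n])
    s = len(known & top)
    p = hypergeom_pmf(EnrichmentQuery(N=population_N, S=len(known), n=top_n, s=s))
    return s, p
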