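"""k-means clustering of embedded points with silhouette-based selection of K.

The number of migration-pattern groups is not known a priori and may change
over time (divisions rearrange cell–cell interactions), so each period is
clustered independently: k-means is run for every candidate K and the K
maximizing the mean silhouette coefficient (MSC) is selected.

k-means is implemented as Lloyd's algorithm with multiple seeded restarts
(the restart minimizing the within-cluster sum of squares, WCSS, wins).
A plain library call would do the same job; the local implementation exists
to expose the per-iteration WCSS trace (the monotone-descent guarantee is
asserted, not assumed) and a deterministic empty-cluster repair rule —
an emptied center is re-seeded at the point farthest from its current
center, which keeps every cluster non-empty.  The test suite cross-checks
both the optimum and the silhouettes against scikit-learn.

The silhouette of point i with within-cluster mean dissimilarity a and
nearest-other-cluster mean dissimilarity b follows the three-branch
definition (1 − a/b if a < b; 0 if a = b; b/a − 1 if a > b), which equals
(b − a)/max(a, b); points in singleton clusters get 0 (a is undefined
there, and 0 is the neutral convention).  Dissimilarity δ is the Euclidean
distance on the embedded points by default; a variant computed directly on
the raw trajectory distance matrix is available via ``precomputed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._seeds import derive_seed
from .errors import ParameterError
from .embedding import EmbeddedPeriod

__all__ = [
    "PeriodClustering",
    "kmeans_cluster",
    "silhouette_values",
    "select_k",
    "cluster_all_periods",
    "write_msc_curves",
]


@dataclass
class PeriodClustering:
    """One k-means result for one period.

    ``msc_curve`` maps each candidate K to its MSC when the instance comes
    out of :func:`select_k` (then ``selected`` is True and ``K`` is the
    argmax, ties broken toward smaller K).
    """

    period: int
    K: int
    labels: np.ndarray  # (N,) cluster index per cell, in cell_order order
    centers: np.ndarray  # (K, 2)
    wcss: float
    silhouettes: np.ndarray | None
    msc: float
    cell_order: list[int]
    selected: bool = False
    msc_curve: dict[int, float] = field(default_factory=dict)
    wcss_history: list[float] = field(default_factory=list)

    def assignment(self) -> dict[int, int]:
        return {cid: int(k) for cid, k in zip(self.cell_order, self.labels)}


def _lloyd(points: np.ndarray, K: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """One restart of Lloyd's algorithm; returns labels, centers, J, J-trace."""
    N = points.shape[0]
    centers = points[rng.choice(N, size=K, replace=False)].copy()
    history: list[float] = []
    labels = np.zeros(N, dtype=int)
    for _ in range(300):
        d2 = cdist(points, centers, "sqeuclidean")
        labels = np.argmin(d2, axis=1)
        # empty-cluster repair: re-seed at the point farthest from its
        # center, never robbing a cluster down to emptiness itself
        for k in range(K):
            if not np.any(labels == k):
                sizes = np.bincount(labels, minlength=K)
                eligible = np.nonzero(sizes[labels] > 1)[0]
                worst = int(eligible[np.argmax(d2[eligible, labels[eligible]])])
                centers[k] = points[worst]
                labels[worst] = k
                d2 = cdist(points, centers, "sqeuclidean")
        J = float(d2[np.arange(N), labels].sum())
        if history and J > history[-1] + 1e-9:
            raise AssertionError("WCSS increased across a Lloyd iteration")
        converged = bool(history) and history[-1] - J <= 1e-12
        history.append(J)
        for k in range(K):
            centers[k] = points[labels == k].mean(axis=0)
        if converged:
            break
    # final J at the updated centers (center updates only ever lower J; the
    # last repaired labels are kept so no cluster is re-emptied by tie-breaks)
    d2 = cdist(points, centers, "sqeuclidean")
    J = float(d2[np.arange(N), labels].sum())
    history.append(J)
    return labels, centers, J, history


def kmeans_cluster(
    e: EmbeddedPeriod, K: int, n_init: int = 50, seed: int = 0
) -> PeriodClustering:
    """Best-of-``n_init`` k-means clustering of one period's embedded points."""
    points = e.points
    N = points.shape[0]
    if not (1 <= K <= N):
        raise ParameterError(f"K={K} outside [1, {N}]")
    if n_init < 1:
        raise ParameterError("n_init must be >= 1")
    best: tuple[np.ndarray, np.ndarray, float, list[float]] | None = None
    for r in range(n_init):
        rng = np.random.default_rng(derive_seed(seed, "restart", r))
        labels, centers, J, history = _lloyd(points, K, rng)
        if best is None or J < best[2]:
            best = (labels, centers, J, history)
    labels, centers, J, history = best
    if K >= 2:
        s, msc = silhouette_values(points, labels)
    else:
        s, msc = None, float("nan")
    return PeriodClustering(
        period=e.period,
        K=K,
        labels=labels,
        centers=centers,
        wcss=J,
        silhouettes=s,
        msc=msc,
        cell_order=list(e.cell_order),
        wcss_history=history,
    )


def silhouette_values(
    points: np.ndarray, labels: Sequence[int], precomputed: bool = False
) -> tuple[np.ndarray, float]:
    """Per-sample silhouettes and their mean (MSC).

    ``points`` is an (N, 2) coordinate array, or an (N, N) dissimilarity
    matrix when ``precomputed`` is True.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ParameterError("silhouette requires at least 2 clusters")
    D = np.asarray(points, float) if precomputed else cdist(points, points)
    N = D.shape[0]
    s = np.zeros(N)
    members = {k: np.nonzero(labels == k)[0] for k in uniq}
    for i in range(N):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0  # a(i) undefined for singletons; neutral convention
            continue
        a = D[i, own].sum() / (own.size - 1)
        b = min(D[i, members[k]].mean() for k in uniq if k != labels[i])
        if a < b:
            s[i] = 1.0 - a / b
        elif a == b:
            s[i] = 0.0
        else:
            s[i] = b / a - 1.0
    return s, float(s.mean())


def select_k(
    e: EmbeddedPeriod,
    k_min: int = 2,
    k_max: int = 10,
    n_init: int = 50,
    seed: int = 0,
    silhouette_on: str = "embedding",
    d=None,
) -> PeriodClustering:
    """Cluster at every K in ``[k_min, k_max]`` and keep the MSC maximizer.

    Ties are broken toward smaller K.  ``silhouette_on="trajectory"`` scores
    each clustering on the raw trajectory distance matrix ``d`` instead of
    the embedded points (non-default variant).
    """
    N = e.points.shape[0]
    if not (2 <= k_min <= k_max <= N - 1):
        raise ParameterError(f"invalid K range [{k_min}, {k_max}] for N={N}")
    if silhouette_on not in ("embedding", "trajectory"):
        raise ParameterError(f"unknown silhouette space: {silhouette_on!r}")
    if silhouette_on == "trajectory" and d is None:
        raise ParameterError("trajectory-space silhouette needs the distance matrix")
    curve: dict[int, float] = {}
    results: dict[int, PeriodClustering] = {}
    for K in range(k_min, k_max + 1):
        c = kmeans_cluster(e, K, n_init=n_init, seed=derive_seed(seed, "K", K))
        if silhouette_on == "trajectory":
            s, msc = silhouette_values(d.values, c.labels, precomputed=True)
            c.silhouettes, c.msc = s, msc
        curve[K] = c.msc
        results[K] = c
    best_k = max(sorted(curve), key=lambda k: curve[k])  # ties -> smaller K
    best = results[best_k]
    best.selected = True
    best.msc_curve = curve
    return best


def cluster_all_periods(
    embeddings: Mapping[int, EmbeddedPeriod],
    k_min: int = 2,
    k_max: int = 10,
    n_init: int = 50,
    seed: int = 0,
) -> dict[int, PeriodClustering]:
    """Independent K selection per period; the selected K may vary over time."""
    if not embeddings:
        raise ParameterError("no periods to cluster")
    out: dict[int, PeriodClustering] = {}
    for p in sorted(embeddings):
        e = embeddings[p]
        kmax = min(k_max, e.points.shape[0] - 1)
        out[p] = select_k(e, k_min, kmax, n_init=n_init, seed=derive_seed(seed, "period", p))
    return out


def write_msc_curves(clusterings: Mapping[int, PeriodClustering], path: str | Path) -> None:
    """CSV of MSC vs K per period, flagging the selected K."""
    rows = []
    for p in sorted(clusterings):
        c = clusterings[p]
        for K in sorted(c.msc_curve):
            rows.append((p, K, c.msc_curve[K], K == c.K))
    pd.DataFrame(rows, columns=["period", "K", "msc", "selected"]).to_csv(path, index=False)
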