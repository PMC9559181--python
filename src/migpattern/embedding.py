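"""2-D embedding of trajectories from the precomputed distance matrix.

Each period's N×N trajectory distance matrix is embedded into two
dimensions with UMAP (primary) or t-SNE (for comparison), always with
``metric="precomputed"`` — the embedders see only the trajectory distances,
never raw coordinates.  Two dimensions keep the representation consistent
with visualization; k-means and the silhouette analysis run on these
embedded points.

Both embedders are stochastic and order-sensitive; the pipeline therefore
fixes a canonical cell order (ascending cell id) upstream and passes an
explicit seed, which makes ``embed`` exactly repeatable.

``sweep_quality`` reproduces the window/parameter selection procedure:
for each candidate observation window and embedding parameter setting it
runs the downstream clustering and reports the mean silhouette coefficient
per period (larger between-cluster separation and tighter clusters give a
larger MSC).  It reports; it does not auto-select.  By default the quality
MSC is evaluated on the *trajectory* distance matrix rather than on the
embedded points: nonlinear embedders exaggerate cluster separation, so
embedding-space silhouettes saturate near 1 for almost any window, while
the raw-metric silhouette genuinely reflects how cleanly a window isolates
migration regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from ._seeds import derive_seed
from .errors import DomainError, ParameterError
from .lineage_division import LineageSet
from .trajectory_distance import TrajectoryDistanceMatrix, distance_matrices
from .trajectory_prep import segment_periods

__all__ = [
    "EmbeddingParams",
    "EmbeddedPeriod",
    "embed",
    "embed_all",
    "sweep_quality",
    "write_embeddings",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Hyperparameters for the 2-D embedders.

    n_neighbors / min_dist apply to UMAP, perplexity to t-SNE; the output
    dimension is fixed at 2.
    """

    n_neighbors: int = 15
    min_dist: float = 0.1
    perplexity: float = 10.0

    def validate(self, n_cells: int, method: str) -> None:
        if method == "umap":
            if not (2 <= self.n_neighbors < n_cells):
                raise ParameterError(
                    f"n_neighbors={self.n_neighbors} invalid for N={n_cells}"
                )
            if not (0.0 <= self.min_dist < 1.0):
                raise ParameterError("min_dist must lie in [0, 1)")
        elif method == "tsne":
            if not (0 < self.perplexity < (n_cells - 1) / 3):
                raise ParameterError(
                    f"perplexity={self.perplexity} invalid for N={n_cells}"
                )
        else:
            raise ParameterError(f"unknown embedding method: {method!r}")

    def clipped(self, n_cells: int) -> "EmbeddingParams":
        """Largest valid setting not exceeding this one, for small N."""
        return replace(
            self,
            n_neighbors=max(2, min(self.n_neighbors, n_cells - 1)),
            perplexity=max(1.0, min(self.perplexity, (n_cells - 1) / 3 - 1e-9)),
        )


@dataclass
class EmbeddedPeriod:
    """N embedded 2-D points for one period (dimensionless embedding units)."""

    period: int
    cell_order: list[int]
    points: np.ndarray  # (N, 2)
    method: str
    params: EmbeddingParams
    seed: int

    def __post_init__(self) -> None:
        if self.points.shape != (len(self.cell_order), 2):
            raise DomainError("points shape inconsistent with cell_order")
        if not np.isfinite(self.points).all():
            raise DomainError("non-finite embedded coordinate")


def embed(
    d: TrajectoryDistanceMatrix,
    method: str = "umap",
    params: EmbeddingParams | None = None,
    seed: int = 0,
) -> EmbeddedPeriod:
    """Embed one period's distance matrix into 2-D.

    Deterministic for identical ``(d, method, params, seed)``.  The matrix is
    used as a precomputed metric; coordinates are never recomputed from it.
    """
    params = params or EmbeddingParams()
    n = d.n_cells
    params.validate(n, method)
    if method == "umap":
        import umap  # deferred: first import JIT-compiles

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_components=2,
                metric="precomputed",
                n_neighbors=params.n_neighbors,
                min_dist=params.min_dist,
                random_state=seed,
            )
            points = reducer.fit_transform(d.values)
    else:
        tsne = TSNE(
            n_components=2,
            metric="precomputed",
            init="random",
            perplexity=params.perplexity,
            random_state=seed,
        )
        points = tsne.fit_transform(d.values)
    return EmbeddedPeriod(d.period, list(d.cell_order), np.asarray(points, float), method, params, seed)


def embed_all(
    matrices: Mapping[int, TrajectoryDistanceMatrix],
    method: str = "umap",
    params: EmbeddingParams | None = None,
    master_seed: int = 0,
) -> dict[int, EmbeddedPeriod]:
    """Embed every period independently, one derived seed per period."""
    return {
        p: embed(matrices[p], method, params, derive_seed(master_seed, "embed", p))
        for p in sorted(matrices)
    }


def sweep_quality(
    lineage: LineageSet,
    window_candidates: Sequence[int],
    param_grid: Iterable[EmbeddingParams] | None = None,
    method: str = "umap",
    seed: int = 0,
    k_min: int = 2,
    k_max: int = 10,
    n_init: int = 10,
    quality_space: str = "trajectory",
) -> pd.DataFrame:
    """Clustering-quality report over observation windows and parameters.

    For every (window, params) combination: segment, normalize, compute
    distances, embed, select the number of clusters per period, and record
    the selected clustering's mean silhouette coefficient — evaluated in
    ``quality_space`` ("trajectory": on the raw distance matrix, the
    default; "embedding": on the embedded points).  Columns include the
    per-period mean and the first/last-period values; rows are sorted by
    decreasing overall mean.  No combination is auto-selected.
    """
    from .clustering_selection import select_k  # deferred: avoid module cycle

    if quality_space not in ("trajectory", "embedding"):
        raise ParameterError(f"unknown quality space: {quality_space!r}")
    windows = list(window_candidates)
    if not windows:
        raise ParameterError("no window candidates given")
    for w in windows:
        if w > lineage.n_slices:
            raise ParameterError(f"candidate window {w} exceeds recording length")
    grid = list(param_grid) if param_grid is not None else [EmbeddingParams()]
    rows = []
    for w in windows:
        periods = segment_periods(lineage, w)
        mats = distance_matrices(periods)
        for params in grid:
            use = params.clipped(periods.n_cells)
            mscs = []
            for p in sorted(mats):
                e = embed(mats[p], method, use, derive_seed(seed, "sweep", w, p))
                kmax = min(k_max, e.points.shape[0] - 1)
                best = select_k(
                    e, k_min, kmax, n_init=n_init,
                    seed=derive_seed(seed, "sweep-k", w, p),
                    silhouette_on=quality_space, d=mats[p],
                )
                mscs.append(best.msc)
            rows.append(
                {
                    "window": w,
                    "n_periods": len(mscs),
                    "n_neighbors": use.n_neighbors,
                    "min_dist": use.min_dist,
                    "perplexity": use.perplexity,
                    "msc_mean": float(np.mean(mscs)),
                    "msc_first": mscs[0],
                    "msc_last": mscs[-1],
                }
            )
    report = pd.DataFrame(rows)
    return report.sort_values("msc_mean", ascending=False).reset_index(drop=True)


def write_embeddings(embeddings: Mapping[int, EmbeddedPeriod], path) -> None:
    """CSV dump ``period,cell_id,dim1,dim2`` over all periods."""
    rows = []
    for p in sorted(embeddings):
        e = embeddings[p]
        for cid, (d1, d2) in zip(e.cell_order, e.points):
            rows.append((p, cid, d1, d2))
    pd.DataFrame(rows, columns=["period", "cell_id", "dim1", "dim2"]).to_csv(path, index=False)
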