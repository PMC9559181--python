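"""Pairwise trajectory distance and the per-period distance matrix.

The dissimilarity between two normalized trajectories of the same period is
the sum over slices of the Euclidean distance between the corresponding
points:

    D(Z_i, Z_j) = Σ_l ‖z_{i,l} − z_{j,l}‖₂ .

Being a sum of per-slice metrics, D is itself a metric (symmetric, zero
diagonal, triangle inequality); it has units of μm summed over the window's
slices (no averaging — averaging by n would only rescale every entry and
leave the clustering unchanged).  The N×N matrix of these distances is the
sole input to the 2-D embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DomainError
from .trajectory_prep import NormalizedTrajectory, PeriodSet

__all__ = [
    "TrajectoryDistanceMatrix",
    "point_distance",
    "trajectory_distance",
    "distance_matrix",
    "distance_matrices",
    "write_matrix",
]


@dataclass
class TrajectoryDistanceMatrix:
    """Symmetric N×N trajectory distance matrix for one period."""

    period: int
    cell_order: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.cell_order):
            raise DomainError("distance matrix shape inconsistent with cell_order")
        if not np.isfinite(v).all():
            raise DomainError("non-finite distance matrix entry")

    @property
    def n_cells(self) -> int:
        return len(self.cell_order)


def point_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two 2-D points (μm)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def trajectory_distance(zi: NormalizedTrajectory, zj: NormalizedTrajectory) -> float:
    """Slice-wise summed Euclidean distance between two normalized trajectories."""
    if zi.offsets.shape != zj.offsets.shape:
        raise DomainError(
            f"trajectory length mismatch: {zi.offsets.shape[0]} vs {zj.offsets.shape[0]}"
        )
    return float(np.linalg.norm(zi.offsets - zj.offsets, axis=1).sum())


def distance_matrix(
    offsets: np.ndarray, period: int, cell_order: Sequence[int]
) -> TrajectoryDistanceMatrix:
    """Distance matrix from an ``(N, n, 2)`` array of normalized offsets.

    Computed slice by slice: the full matrix is the sum over slices of the
    pairwise point-distance matrices.
    """
    if offsets.ndim != 3 or offsets.shape[2] != 2:
        raise DomainError("offsets must be an (N, n, 2) array")
    N = offsets.shape[0]
    if N < 2:
        raise DomainError("need at least two trajectories")
    values = np.zeros((N, N))
    for l in range(offsets.shape[1]):
        values += cdist(offsets[:, l, :], offsets[:, l, :])
    # enforce exact symmetry and zero diagonal against floating-point drift
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return TrajectoryDistanceMatrix(period, list(cell_order), values)


def distance_matrices(periods: PeriodSet) -> dict[int, TrajectoryDistanceMatrix]:
    """One distance matrix per period, rows in canonical (ascending id) order."""
    return {
        p: distance_matrix(periods.normalized[p], p, periods.cell_ids)
        for p in periods.periods
    }


def write_matrix(d: TrajectoryDistanceMatrix, path: str | Path) -> None:
    """Dump a matrix as CSV with the cell order as header row and column."""
    df = pd.DataFrame(d.values, index=d.cell_order, columns=d.cell_order)
    df.to_csv(path, index_label="cell_id")
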