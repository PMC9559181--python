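"""Period segmentation and origin normalization of cell trajectories.

The recording is split into contiguous, non-overlapping observation windows
("periods") of ``n`` slices each; period ``p`` (1-based) covers slices
``[(p-1)*n, p*n)`` and trailing slices beyond the last complete window are
dropped.  With the reference recording of 97 slices (24 h at 15-min
intervals) and the default 12-slice window this yields 8 periods.

Within each period, every trajectory is translated so that its first
position lies at the origin.  This removes the absolute colony position
from the comparison: two cells far apart that move the same way have
identical normalized trajectories.  No rotation or scale normalization is
applied — direction and speed are part of the migration pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ParameterError
from .lineage_division import LineageSet
from .tracking_io import Phenotype

__all__ = [
    "PeriodTrajectory",
    "NormalizedTrajectory",
    "PeriodSet",
    "segment_periods",
    "normalize_period",
]


@dataclass(frozen=True)
class PeriodTrajectory:
    """One cell's raw (pre-normalization) trajectory within one period."""

    cell_id: int
    period: int
    positions: np.ndarray  # (n, 2), μm

    def __post_init__(self) -> None:
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise DomainError("positions must be an (n, 2) array")


@dataclass(frozen=True)
class NormalizedTrajectory:
    """One cell's origin-anchored trajectory: offsets from its first position."""

    cell_id: int
    period: int
    offsets: np.ndarray  # (n, 2), μm; offsets[0] == (0, 0)


def normalize_period(v: PeriodTrajectory) -> NormalizedTrajectory:
    """Translate a period trajectory so its initial position is the origin.

    The result is invariant under any constant translation of the input
    (exactly, in floating point: the same subtraction is performed).
    """
    offsets = v.positions - v.positions[0]
    return NormalizedTrajectory(v.cell_id, v.period, offsets)


@dataclass
class PeriodSet:
    """All cells' raw and normalized trajectories for every complete period.

    ``raw[p]`` and ``normalized[p]`` are ``(N, n, 2)`` arrays with rows in
    ``cell_ids`` order (ascending id, the pipeline's canonical order).
    """

    n: int
    cell_ids: list[int]
    raw: dict[int, np.ndarray]
    normalized: dict[int, np.ndarray]
    phenotypes: dict[int, Phenotype] = field(default_factory=dict)

    @property
    def n_periods(self) -> int:
        return len(self.raw)

    @property
    def periods(self) -> list[int]:
        return sorted(self.raw)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def trajectory(self, period: int, cell_id: int) -> PeriodTrajectory:
        i = self.cell_ids.index(cell_id)
        return PeriodTrajectory(cell_id, period, self.raw[period][i])

    def normalized_trajectory(self, period: int, cell_id: int) -> NormalizedTrajectory:
        i = self.cell_ids.index(cell_id)
        return NormalizedTrajectory(cell_id, period, self.normalized[period][i])


def segment_periods(lineage: LineageSet, n: int = 12) -> PeriodSet:
    """Cut full-length leaf trajectories into ``floor(T / n)`` periods.

    Raises
    ------
    ParameterError
        If ``n < 2``.
    DomainError
        If the recording is shorter than one window (``T < n``).
    """
    if n < 2:
        raise ParameterError("window length n must be >= 2")
    T = lineage.n_slices
    if T < n:
        raise DomainError(f"recording has {T} slices, shorter than one window of {n}")
    n_periods = T // n
    cell_ids = lineage.cell_ids
    stacked = lineage.positions(cell_ids)  # (N, T, 2)
    raw: dict[int, np.ndarray] = {}
    normalized: dict[int, np.ndarray] = {}
    for p in range(1, n_periods + 1):
        window = stacked[:, (p - 1) * n : p * n, :]
        raw[p] = window.copy()
        normalized[p] = window - window[:, :1, :]
    return PeriodSet(
        n=n,
        cell_ids=list(cell_ids),
        raw=raw,
        normalized=normalized,
        phenotypes=dict(lineage.phenotypes),
    )
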