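"""Seeded synthetic colonies with the statistical structure the analysis assumes.

The generator emulates a time-lapse recording of a migrating colony on
aligned fibers: a few tens of founder cells, tracked at 15-min intervals
for ~24 h, moving outward in a small number of migration-pattern *groups*.
Every cell in a group shares the group's per-slice drift vector (the
leader–follower coordination the clustering is meant to recover), stretched
along the x axis to mimic fiber-aligned anisotropy, plus independent
isotropic Gaussian wander; each step is clipped so that no per-step
displacement exceeds ``step_cap``.  At a division the mother's track ends
and two daughter tracks begin on the next slice, placed symmetrically at
±``division_separation``/2 across the mother's last position, perpendicular
to the group's drift — producing the clean above-10-μm daughter separation
that makes divisions detectable while every ordinary step stays at most
6 μm.  A minority of cells carries the mesenchymal (TGF-treated) phenotype,
spread across distinct groups; phenotype is inherited by daughters and
never influences motion (the analysis must be blind to it).

Everything is reproducible: the same config and seed give byte-identical
track tables.  ``GroundTruth`` carries the planted group labels, phenotypes,
drift vectors and division events for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .lineage_division import DivisionEvent
from .tracking_io import Phenotype, TrackTable

__all__ = ["ColonyConfig", "GroundTruth", "generate_colony", "generate_separable_groups"]


@dataclass(frozen=True)
class ColonyConfig:
    """Parameters of the synthetic colony.

    Defaults mirror the reference recording: 28 founders growing to ~90
    leaves over 97 slices at 15-min intervals, per-step displacements capped
    at 6 μm, and daughter separation of 12 μm (> the 10-μm jump threshold).
    """

    n_founders: int = 28
    n_slices: int = 97
    slice_interval_minutes: float = 15.0
    n_groups: int = 4
    leader_fraction: float = 0.2
    drift_per_group: Optional[np.ndarray] = None  # (G, 2) μm/slice; None -> radial
    drift_magnitude: float = 1.5  # μm/slice, pre-anisotropy, when drifts are derived
    follower_noise_std: float = 0.8  # μm per coordinate per step
    step_cap: float = 6.0  # μm
    anisotropy: float = 3.0  # x-elongation of drift (fiber axis)
    division_rate: float = 0.0125  # per cell per slice; grows 28 -> ~92 over 96 steps
    division_schedule: Optional[tuple[tuple[int, int], ...]] = None  # (cell, slice)
    division_separation: float = 12.0  # μm between daughters at the division slice
    colony_radius: float = 25.0  # μm, founder placement disc

    def validate(self) -> None:
        if self.n_founders < 2 or self.n_slices < 2:
            raise ParameterError("need at least 2 founders and 2 slices")
        if not (0.0 < self.leader_fraction < 1.0):
            raise ParameterError("leader_fraction must lie in (0, 1)")
        if not (self.division_separation > 10.0 > self.step_cap):
            raise ParameterError(
                "separability requires division_separation > 10 > step_cap"
            )
        if self.n_groups < 1:
            raise ParameterError("need at least one group")
        if self.anisotropy < 1.0:
            raise ParameterError("anisotropy must be >= 1")
        if self.division_rate < 0:
            raise ParameterError("division_rate must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure of a generated colony."""

    group_of_cell: dict[int, int]
    phenotype_of_cell: dict[int, Phenotype]
    division_events: list[DivisionEvent]
    drift_vectors: np.ndarray  # (G, 2) effective (post-anisotropy) μm/slice

    def leaf_groups(self, cell_ids: Sequence[int]) -> np.ndarray:
        return np.asarray([self.group_of_cell[c] for c in cell_ids])


def _derived_drifts(config: ColonyConfig) -> np.ndarray:
    """Evenly spaced drift directions, elongated along the fiber (x) axis."""
    if config.drift_per_group is not None:
        drifts = np.asarray(config.drift_per_group, float).copy()
        if drifts.shape != (config.n_groups, 2):
            raise ParameterError("drift_per_group must have shape (n_groups, 2)")
    else:
        angles = 2 * np.pi * (np.arange(config.n_groups) + 0.5) / config.n_groups
        drifts = config.drift_magnitude * np.column_stack([np.cos(angles), np.sin(angles)])
    drifts[:, 0] *= config.anisotropy
    return drifts


def generate_colony(
    config: ColonyConfig | None = None, seed: int = 0
) -> tuple[TrackTable, GroundTruth]:
    """Simulate one colony; returns the raw track table and its ground truth.

    The table is in raw form: a dividing mother's track ends and two new
    daughter tracks begin on the next slice (division detection and lineage
    unification are exercised downstream).
    """
    config = config or ColonyConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    G = config.n_groups
    drifts = _derived_drifts(config)

    # founders: uniform in a disc, groups round-robin over a shuffled order,
    # leaders (mesenchymal phenotype) spread over distinct groups
    n0 = config.n_founders
    r = config.colony_radius * np.sqrt(rng.random(n0))
    th = rng.random(n0) * 2 * np.pi
    pos0 = np.column_stack([r * np.cos(th), r * np.sin(th)])
    order = rng.permutation(n0)
    group_of: dict[int, int] = {int(cid): int(i % G) for i, cid in enumerate(order)}
    n_leaders = max(1, round(config.leader_fraction * n0))
    pheno_of: dict[int, Phenotype] = {cid: Phenotype.TGF_MINUS for cid in range(n0)}
    for i in range(n_leaders):
        pheno_of[int(order[i])] = Phenotype.TGF_PLUS  # round-robin ⇒ distinct groups

    schedule = set(config.division_schedule or ())
    rows: list[tuple[int, int, float, float, str]] = []
    active: dict[int, np.ndarray] = {cid: pos0[cid].copy() for cid in range(n0)}
    next_id = n0
    events: list[DivisionEvent] = []
    for cid, p in active.items():
        rows.append((cid, 0, float(p[0]), float(p[1]), pheno_of[cid].value))

    for sl in range(1, config.n_slices):
        # decide divisions first (a cell divides *into* this slice)
        dividing = []
        for cid in sorted(active):
            planted = (cid, sl) in schedule
            stochastic = (
                config.division_schedule is None
                and config.division_rate > 0
                and rng.random() < config.division_rate
            )
            if planted or stochastic:
                dividing.append(cid)
        born: set[int] = set()
        for cid in dividing:
            mother_pos = active.pop(cid)
            g = group_of[cid]
            drift = drifts[g]
            norm = np.linalg.norm(drift)
            if norm > 0:
                perp = np.array([-drift[1], drift[0]]) / norm
            else:
                ang = rng.random() * 2 * np.pi
                perp = np.array([math.cos(ang), math.sin(ang)])
            offset = perp * config.division_separation / 2.0
            d1, d2 = next_id, next_id + 1
            next_id += 2
            for did, s in ((d1, +1.0), (d2, -1.0)):
                active[did] = mother_pos + s * offset
                group_of[did] = g
                pheno_of[did] = pheno_of[cid]
                born.add(did)
            events.append(DivisionEvent(cid, (d1, d2), sl))
        # everyone else takes a drift + wander step, clipped to the cap
        for cid in sorted(active):
            if cid in born:
                continue  # daughters appear at their birth position this slice
            step = drifts[group_of[cid]] + rng.normal(0.0, config.follower_noise_std, 2)
            norm = float(np.linalg.norm(step))
            if norm > config.step_cap:
                step *= config.step_cap / norm
            active[cid] = active[cid] + step
        for cid in sorted(active):
            p = active[cid]
            rows.append((cid, sl, float(p[0]), float(p[1]), pheno_of[cid].value))

    df = pd.DataFrame(rows, columns=["cell_id", "slice", "x", "y", "phenotype"])
    table = TrackTable(df, config.slice_interval_minutes, config.n_slices)
    truth = GroundTruth(
        group_of_cell=group_of,
        phenotype_of_cell=pheno_of,
        division_events=events,
        drift_vectors=drifts,
    )
    return table, truth


def generate_separable_groups(
    config: ColonyConfig | None = None,
    separation_factor: float = 3.0,
    seed: int = 0,
) -> tuple[TrackTable, GroundTruth]:
    """Colony preset whose group drifts scale with ``separation_factor``.

    The drift magnitude is set to ``separation_factor`` times the per-step
    wander, so between-group trajectory distances (which grow linearly in
    the drift gap over a window) dominate within-group distances (noise
    accumulation) by roughly that factor.  Large factors give cleanly
    recoverable groups; factors near zero are a negative control in which
    the groups are statistically indistinguishable.
    """
    if separation_factor <= 0:
        raise ParameterError("separation_factor must be positive")
    config = config or ColonyConfig()
    config = replace(
        config,
        drift_per_group=None,
        drift_magnitude=separation_factor * config.follower_noise_std,
    )
    return generate_colony(config, seed)
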