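"""Cell-division detection and mother/daughter trajectory unification.

Dividing cells break the premise that every cell has one trajectory over the
whole recording.  The convention adopted here (and standard for
backward-tracked time-lapse data) is to treat every cell present in the
*last* slice as a leaf, and to extend each leaf's trajectory backwards
through its ancestors, so that the two daughters of a division share the
mother's positions at all slices before the division.  The result is one
full-length trajectory per leaf cell, which is what the period segmentation
consumes.

Division events are detected from marker-point geometry alone.  Two signals
are used, reflecting the separation printed for the reference data (per-step
displacements at most ~6 μm, daughter separation above 10 μm right after
division):

* tracks that *end* before the last slice are candidate mothers; a pair of
  tracks starting on the next slice, at least ``jump_threshold`` apart and
  centred on the mother's last position, is a daughter pair;
* for tables that already contain full-length unified tracks, a pair of
  distinct cell ids whose mutual distance is below ``proximity_threshold``
  on one slice and at least ``jump_threshold`` on the next marks a division
  at the latter slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError, ParameterError
from .tracking_io import Phenotype, TrackTable

# Unified daughters carry exact copies of the mother's positions, so their
# pre-division distance is zero up to CSV round-trip precision (1e-6 μm).
_COINCIDENCE_TOL = 1e-5

__all__ = [
    "DivisionEvent",
    "LineageSet",
    "pair_distance_series",
    "step_sizes",
    "detect_divisions",
    "unify_lineage",
    "write_lineage",
    "render_lineage_tree",
]


@dataclass(frozen=True)
class DivisionEvent:
    """One division: ``division_slice`` is the first slice at which the two
    daughters are distinct points.  ``mother_id`` is ``None`` when the input
    table holds already-unified full-length tracks, where the mother has no
    separate id."""

    mother_id: Optional[int]
    daughter_ids: tuple[int, int]
    division_slice: int

    def __post_init__(self) -> None:
        if self.daughter_ids[0] == self.daughter_ids[1]:
            raise IntegrityError("daughter ids must be distinct")
        if self.division_slice < 1:
            raise IntegrityError("division_slice must be >= 1")


@dataclass
class LineageSet:
    """Unified lineage: full-length leaf trajectories plus the division tree.

    ``trajectories[cell_id]`` is a ``(T, 2)`` array covering every slice of
    the recording; ``parent`` maps each non-founder cell to its mother
    (a forest: one mother per cell at most).
    """

    n_slices: int
    trajectories: dict[int, np.ndarray]
    events: list[DivisionEvent] = field(default_factory=list)
    parent: dict[int, Optional[int]] = field(default_factory=dict)
    phenotypes: dict[int, Phenotype] = field(default_factory=dict)
    slice_interval_minutes: float = 15.0

    def __post_init__(self) -> None:
        for cid, traj in self.trajectories.items():
            if traj.shape != (self.n_slices, 2):
                raise IntegrityError(
                    f"leaf trajectory of cell {cid} has shape {traj.shape}, "
                    f"expected ({self.n_slices}, 2)"
                )

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.trajectories)

    @property
    def n_cells(self) -> int:
        return len(self.trajectories)

    def positions(self, cell_order: Sequence[int] | None = None) -> np.ndarray:
        """Stack leaf trajectories into an ``(N, T, 2)`` array."""
        order = list(cell_order) if cell_order is not None else self.cell_ids
        return np.stack([self.trajectories[c] for c in order])

    def with_positions(self, stacked: np.ndarray, cell_order: Sequence[int] | None = None) -> "LineageSet":
        """Return a copy with replaced positions (same cells and metadata)."""
        order = list(cell_order) if cell_order is not None else self.cell_ids
        if stacked.shape != (len(order), self.n_slices, 2):
            raise IntegrityError("position array shape mismatch")
        return LineageSet(
            n_slices=self.n_slices,
            trajectories={c: stacked[i].copy() for i, c in enumerate(order)},
            events=list(self.events),
            parent=dict(self.parent),
            phenotypes=dict(self.phenotypes),
            slice_interval_minutes=self.slice_interval_minutes,
        )


def pair_distance_series(table: TrackTable, id_a: int, id_b: int) -> np.ndarray:
    """Euclidean distance between two cells' marker points per shared slice."""
    sa, pa = table.track(id_a)
    sb, pb = table.track(id_b)
    shared, ia, ib = np.intersect1d(sa, sb, return_indices=True)
    if shared.size == 0:
        raise DomainError(f"cells {id_a} and {id_b} share no slices")
    return np.linalg.norm(pa[ia] - pb[ib], axis=1)


def step_sizes(table: TrackTable, cell_id: int) -> np.ndarray:
    """Per-step displacement of one cell (length = track length − 1)."""
    _, pos = table.track(cell_id)
    if len(pos) < 2:
        raise DomainError(f"track of cell {cell_id} is shorter than 2 slices")
    return np.linalg.norm(np.diff(pos, axis=0), axis=1)


def detect_divisions(
    table: TrackTable,
    jump_threshold: float = 10.0,
    proximity_threshold: float = 6.0,
    mode: str = "auto",
) -> list[DivisionEvent]:
    """Detect division events from marker-point distances.

    The jump threshold must exceed the proximity threshold: the separability
    between the largest per-step displacement and the post-division daughter
    separation is what makes divisions detectable from geometry alone.

    Two table forms are handled, selected automatically (``mode="auto"``)
    from the track spans:

    * ``ended_tracks`` — raw tables where the mother track ends and two
      daughter tracks begin on the next slice, at least ``jump_threshold``
      apart and centred (within ``proximity_threshold``) on the mother's
      last position;
    * ``coincident_pairs`` — already-unified tables where every track spans
      the whole recording; a pair of ids whose marker points *coincide* on
      every slice before ``l`` and are at least ``jump_threshold`` apart at
      ``l`` divides at ``l``.  Unified daughters carry copies of the
      mother's positions before the division, so their pre-division distance
      is numerically zero; requiring coincidence (rather than mere
      proximity) prevents transient near-passes of unrelated cells from
      being read as divisions.
    """
    if jump_threshold <= 0 or proximity_threshold <= 0:
        raise ParameterError("thresholds must be positive")
    if jump_threshold <= proximity_threshold:
        raise ParameterError("jump_threshold must exceed proximity_threshold")
    if mode not in ("auto", "ended_tracks", "coincident_pairs"):
        raise ParameterError(f"unknown detection mode: {mode!r}")

    spans = {cid: table.span(cid) for cid in table.cell_ids}
    last = table.n_slices - 1
    if mode == "auto":
        full_span = all(s0 == 0 and s1 == last for s0, s1 in spans.values())
        mode = "coincident_pairs" if full_span else "ended_tracks"

    events: list[DivisionEvent] = []
    used_daughters: set[tuple[int, int]] = set()  # (cell_id, slice)

    if mode == "ended_tracks":
        mothers = [cid for cid, (s0, s1) in spans.items() if s1 < last]
        starters: dict[int, list[int]] = {}
        for cid, (s0, _) in spans.items():
            starters.setdefault(s0, []).append(cid)
        candidates: list[tuple[float, int, int, int, int]] = []
        for m in mothers:
            _, m_end = spans[m]
            m_last = table.track(m)[1][-1]
            sl = m_end + 1
            group = starters.get(sl, [])
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    a, b = group[i], group[j]
                    pa = table.track(a)[1][0]
                    pb = table.track(b)[1][0]
                    if np.linalg.norm(pa - pb) < jump_threshold:
                        continue
                    mid = (pa + pb) / 2.0
                    gap = float(np.linalg.norm(mid - m_last))
                    if gap <= proximity_threshold:
                        candidates.append((gap, m, a, b, sl))
        used_mothers: set[int] = set()
        for gap, m, a, b, sl in sorted(candidates):
            if m in used_mothers or (a, sl) in used_daughters or (b, sl) in used_daughters:
                continue
            used_mothers.add(m)
            used_daughters.update({(a, sl), (b, sl)})
            events.append(DivisionEvent(m, (min(a, b), max(a, b)), sl))
    else:
        ids = table.cell_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = ids[i], ids[j]
                (a0, a1), (b0, b1) = spans[a], spans[b]
                lo, hi = max(a0, b0), min(a1, b1)
                if hi - lo < 1:
                    continue
                d = pair_distance_series(table, a, b)
                jumps = np.nonzero(d >= jump_threshold)[0]
                if jumps.size == 0:
                    continue
                first = int(jumps[0])
                if first == 0 or not np.all(d[:first] < _COINCIDENCE_TOL):
                    continue
                sl = int(lo + first)
                if (a, sl) in used_daughters or (b, sl) in used_daughters:
                    continue
                used_daughters.update({(a, sl), (b, sl)})
                events.append(DivisionEvent(None, (a, b), sl))

    events.sort(key=lambda e: (e.division_slice, e.daughter_ids))
    return events


def unify_lineage(table: TrackTable, events: Sequence[DivisionEvent]) -> LineageSet:
    """Build full-length leaf trajectories by copying ancestral positions.

    Every cell present in the last slice becomes a leaf; slices before a
    division are filled from the mother, recursively through nested
    divisions.  Every original marker point survives in at least one leaf.
    """
    T = table.n_slices
    last = T - 1
    known = set(table.cell_ids)
    for ev in events:
        refs = set(ev.daughter_ids) | ({ev.mother_id} if ev.mother_id is not None else set())
        unknown = refs - known
        if unknown:
            raise IntegrityError(f"division event references unknown cell(s): {sorted(unknown)}")

    spans = {cid: table.span(cid) for cid in table.cell_ids}
    leaves = [cid for cid, (s0, s1) in spans.items() if s1 == last]
    by_daughter = {}
    parent: dict[int, Optional[int]] = {}
    for ev in events:
        if ev.mother_id is None:
            continue
        m_end = spans[ev.mother_id][1]
        if not (ev.division_slice - 2 <= m_end <= ev.division_slice):
            raise IntegrityError(
                f"mother {ev.mother_id} track ends at slice {m_end}, inconsistent "
                f"with division at slice {ev.division_slice}"
            )
        for d in ev.daughter_ids:
            if d in by_daughter:
                raise IntegrityError(f"cell {d} is daughter of more than one division")
            by_daughter[d] = ev
            parent[d] = ev.mother_id

    trajectories: dict[int, np.ndarray] = {}
    for leaf in sorted(leaves):
        traj = np.full((T, 2), np.nan)
        cur: Optional[int] = leaf
        upper = T  # fill slices [.., upper)
        while cur is not None:
            s0, s1 = spans[cur]
            sl, pos = table.track(cur)
            lo = s0
            hi = min(s1, upper - 1)
            if hi >= lo:
                traj[lo : hi + 1] = pos[lo - s0 : hi - s0 + 1]
            ev = by_daughter.get(cur)
            if ev is None:
                if lo > 0:
                    raise IntegrityError(
                        f"track of cell {cur} starts at slice {lo} with no recorded mother"
                    )
                cur = None
            else:
                # daughter records before the division must agree with the mother
                if s0 < ev.division_slice:
                    m_sl, m_pos = table.track(ev.mother_id)
                    for s in range(s0, min(ev.division_slice, s1 + 1)):
                        if s in m_sl:
                            mp = m_pos[s - m_sl[0]]
                            if not np.allclose(traj[s], mp, atol=1e-9):
                                raise IntegrityError(
                                    f"daughter {cur} conflicts with mother "
                                    f"{ev.mother_id} at slice {s}"
                                )
                upper = ev.division_slice
                cur = ev.mother_id
        if np.isnan(traj).any():
            missing = int(np.nonzero(np.isnan(traj[:, 0]))[0][0])
            raise IntegrityError(f"leaf {leaf} has no ancestral position at slice {missing}")
        trajectories[leaf] = traj

    # mother-less (already unified) events: force the daughters' shared
    # prefix to be exactly identical so downstream invariants hold bitwise
    for ev in events:
        if ev.mother_id is not None:
            continue
        a, b = ev.daughter_ids
        if a in trajectories and b in trajectories:
            sl = ev.division_slice
            if not np.allclose(trajectories[a][:sl], trajectories[b][:sl], atol=1e-6):
                raise IntegrityError(
                    f"pre-division trajectories of {a} and {b} disagree"
                )
            trajectories[b][:sl] = trajectories[a][:sl]
            parent.setdefault(a, None)
            parent.setdefault(b, None)

    phenos = {cid: table.phenotype_of(cid) for cid in trajectories}
    for cid in trajectories:
        parent.setdefault(cid, None)
    return LineageSet(
        n_slices=T,
        trajectories=trajectories,
        events=list(events),
        parent={c: parent.get(c) for c in sorted(set(parent) | set(trajectories))},
        phenotypes=phenos,
        slice_interval_minutes=table.slice_interval_minutes,
    )


def write_lineage(lineage: LineageSet, path: str | Path) -> None:
    """CSV ``cell_id,mother_id,division_slice`` (mother empty for founders)."""
    by_daughter: dict[int, DivisionEvent] = {}
    for ev in lineage.events:
        for d in ev.daughter_ids:
            by_daughter[d] = ev
    rows = []
    for cid in sorted(set(lineage.parent) | set(lineage.trajectories)):
        ev = by_daughter.get(cid)
        mother = lineage.parent.get(cid)
        rows.append(
            (
                cid,
                "" if mother is None else mother,
                "" if ev is None else ev.division_slice,
            )
        )
    pd.DataFrame(rows, columns=["cell_id", "mother_id", "division_slice"]).to_csv(
        path, index=False
    )


def render_lineage_tree(lineage: LineageSet) -> str:
    """Plain-text indented rendering of the division forest."""
    children: dict[Optional[int], list[int]] = {}
    mothers = {m for m in lineage.parent.values() if m is not None}
    all_cells = sorted(set(lineage.parent) | set(lineage.trajectories) | mothers)
    for cid in all_cells:
        children.setdefault(lineage.parent.get(cid), []).append(cid)
    lines: list[str] = []

    def walk(cid: int, depth: int) -> None:
        lines.append("  " * depth + f"cell {cid}")
        for child in sorted(children.get(cid, [])):
            walk(child, depth + 1)

    for root in sorted(children.get(None, [])):
        walk(root, 0)
    return "\n".join(lines)
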