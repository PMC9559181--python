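"""Reading, validating and writing per-slice cell tracking tables.

The pipeline's raw input is a table of nucleus marker points: one row per
(cell, time slice) with a 2-D position in micrometres and an optional
phenotype label (TGF-beta-treated mesenchymal cells vs. untreated epithelial
cells).  Two CSV dialects are supported: a minimal ``simple_csv`` dialect and
a TrackMate-spot-export-like dialect (``trackmate_csv``).  All tables are
validated on construction: (cell, slice) pairs are unique, positions are
finite, and each cell's slice set is a contiguous range (a track has no
gaps — tracking software either follows a cell or loses it).

Internally slices are 0-based; inputs whose minimum slice is non-zero are
re-based on read.  Positions are Cartesian micrometres; because every
downstream quantity is translation-normalized, the image-origin convention
of the source data is irrelevant and accepted as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, ParameterError

__all__ = [
    "Phenotype",
    "TrackRecord",
    "TrackTable",
    "read_tracks",
    "write_tracks",
    "write_assignments",
    "read_assignments",
]


class Phenotype(str, Enum):
    """Reported cell phenotype; never used in any computation."""

    TGF_PLUS = "TGF_PLUS"
    TGF_MINUS = "TGF_MINUS"
    UNKNOWN = "UNKNOWN"

    @classmethod
    def parse(cls, value: object) -> "Phenotype":
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return cls.UNKNOWN
        text = str(value).strip().upper().replace("-", "_").replace("(", "").replace(")", "")
        aliases = {
            "TGF+": cls.TGF_PLUS,
            "TGF_PLUS": cls.TGF_PLUS,
            "TGFPLUS": cls.TGF_PLUS,
            "TGF_": cls.TGF_MINUS,
            "TGF_MINUS": cls.TGF_MINUS,
            "TGFMINUS": cls.TGF_MINUS,
            "": cls.UNKNOWN,
            "UNKNOWN": cls.UNKNOWN,
        }
        if text in aliases:
            return aliases[text]
        raise FormatError(f"unrecognized phenotype label: {value!r}")


@dataclass(frozen=True)
class TrackRecord:
    """A single marker point: one cell at one time slice."""

    cell_id: int
    slice: int
    x: float
    y: float
    phenotype: Phenotype = Phenotype.UNKNOWN


_COLUMNS = ["cell_id", "slice", "x", "y", "phenotype"]

# TrackMate spot-export header names mapped onto our schema.
_TRACKMATE_MAP = {
    "TRACK_ID": "cell_id",
    "FRAME": "slice",
    "POSITION_X": "x",
    "POSITION_Y": "y",
}


@dataclass
class TrackTable:
    """Validated collection of tracking records.

    Parameters
    ----------
    df
        DataFrame with columns ``cell_id, slice, x, y, phenotype``; one row
        per marker point.  Rows are kept sorted by (cell_id, slice).
    slice_interval_minutes
        Real time between adjacent slices (15 min in the reference setup).
    n_slices
        Total number of recorded slices T; all slice indices lie in
        ``[0, n_slices)``.
    """

    df: pd.DataFrame
    slice_interval_minutes: float = 15.0
    n_slices: int = field(default=0)

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        df = self.df.loc[:, _COLUMNS].copy()
        df["cell_id"] = df["cell_id"].astype(np.int64)
        df["slice"] = df["slice"].astype(np.int64)
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
        df["phenotype"] = [Phenotype.parse(v).value for v in df["phenotype"]]
        df = df.sort_values(["cell_id", "slice"], kind="mergesort").reset_index(drop=True)
        if self.slice_interval_minutes <= 0:
            raise ParameterError("slice_interval_minutes must be positive")
        if not np.isfinite(df[["x", "y"]].to_numpy()).all():
            raise IntegrityError("non-finite position encountered")
        dup = df.duplicated(subset=["cell_id", "slice"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["cell_id", "slice"]]
            raise IntegrityError(
                f"duplicate (cell_id, slice) pair: ({pair.cell_id}, {pair.slice})"
            )
        if len(df) and df["slice"].min() < 0:
            raise IntegrityError("negative slice index")
        inferred = int(df["slice"].max()) + 1 if len(df) else 0
        if self.n_slices == 0:
            self.n_slices = inferred
        elif inferred > self.n_slices:
            raise IntegrityError(
                f"slice index {inferred - 1} outside [0, {self.n_slices})"
            )
        # contiguity per track
        for cid, grp in df.groupby("cell_id", sort=False):
            s = grp["slice"].to_numpy()
            if len(s) and (s[-1] - s[0] + 1 != len(s)):
                raise IntegrityError(f"track of cell {cid} has a gap in its slice range")
        self.df = df

    # -- accessors ---------------------------------------------------------

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.df["cell_id"].unique().tolist())

    def track(self, cell_id: int) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(slices, positions)`` for one cell; positions is (L, 2)."""
        grp = self.df[self.df["cell_id"] == cell_id]
        if grp.empty:
            raise IntegrityError(f"unknown cell_id {cell_id}")
        return grp["slice"].to_numpy(), grp[["x", "y"]].to_numpy()

    def span(self, cell_id: int) -> tuple[int, int]:
        """First and last slice of a cell's track (inclusive)."""
        s, _ = self.track(cell_id)
        return int(s[0]), int(s[-1])

    def phenotype_of(self, cell_id: int) -> Phenotype:
        grp = self.df[self.df["cell_id"] == cell_id]
        if grp.empty:
            raise IntegrityError(f"unknown cell_id {cell_id}")
        return Phenotype(grp["phenotype"].iloc[0])

    def records(self) -> Iterable[TrackRecord]:
        for row in self.df.itertuples(index=False):
            yield TrackRecord(row.cell_id, row.slice, row.x, row.y, Phenotype(row.phenotype))

    def translated(self, dx: float, dy: float) -> "TrackTable":
        """Rigidly translate every position (used for invariance checks)."""
        df = self.df.copy()
        df["x"] += dx
        df["y"] += dy
        return TrackTable(df, self.slice_interval_minutes, self.n_slices)


def _from_frame(df: pd.DataFrame, slice_interval_minutes: float) -> TrackTable:
    # re-base slices so the recording starts at 0
    if len(df):
        df["slice"] = df["slice"] - int(df["slice"].min())
    return TrackTable(df, slice_interval_minutes=slice_interval_minutes)


def read_tracks(
    path: str | Path,
    dialect: str = "simple_csv",
    slice_interval_minutes: float = 15.0,
) -> TrackTable:
    """Read a tracking table from CSV.

    ``simple_csv`` expects a header ``cell_id,slice,x,y[,phenotype]``.
    ``trackmate_csv`` tolerates TrackMate spot-export headers (``TRACK_ID``,
    ``FRAME``, ``POSITION_X``, ``POSITION_Y``) including the non-numeric
    repeat-header rows that TrackMate writes below the header line.
    Slice indices are re-based to start at 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "simple_csv":
        raw = pd.read_csv(path)
        for col in ("cell_id", "slice", "x", "y"):
            if col not in raw.columns:
                raise FormatError(f"missing required column(s): {col}")
        if "phenotype" not in raw.columns:
            raw["phenotype"] = Phenotype.UNKNOWN.value
        df = raw.loc[:, _COLUMNS]
    elif dialect == "trackmate_csv":
        raw = pd.read_csv(path)
        for col in _TRACKMATE_MAP:
            if col not in raw.columns:
                raise FormatError(f"missing required column(s): {col}")
        # TrackMate exports repeat the header as extra descriptive rows.
        numeric = pd.to_numeric(raw["FRAME"], errors="coerce")
        raw = raw[numeric.notna()].copy()
        df = raw.rename(columns=_TRACKMATE_MAP).loc[:, list(_TRACKMATE_MAP.values())]
        df = df.apply(pd.to_numeric)
        df["phenotype"] = Phenotype.UNKNOWN.value
        df = df.loc[:, _COLUMNS[:4] + ["phenotype"]]
        df.columns = _COLUMNS
    else:
        raise ParameterError(f"unknown dialect: {dialect!r}")
    return _from_frame(df, slice_interval_minutes)


def write_tracks(table: TrackTable, path: str | Path) -> None:
    """Write a table as ``simple_csv`` with deterministic row order.

    Positions are written with 6 decimal places, which round-trips losslessly
    at the sub-nanometre level — far below tracking precision.
    """
    path = Path(path)
    df = table.df.sort_values(["cell_id", "slice"], kind="mergesort")
    df.to_csv(path, index=False, float_format="%.6f")


def write_assignments(
    assignments: Mapping[int, Mapping[int, int]],
    path: str | Path,
    phenotypes: Mapping[int, Phenotype] | None = None,
) -> None:
    """Write per-period cluster assignments as long-format CSV.

    ``assignments[period][cell_id] -> cluster``.  Every period must cover the
    same cell set (the unified lineage guarantees this upstream).
    """
    periods = sorted(assignments)
    if not periods:
        raise IntegrityError("no periods to write")
    base = set(assignments[periods[0]])
    for p in periods[1:]:
        if set(assignments[p]) != base:
            raise IntegrityError(f"cell set of period {p} differs from period {periods[0]}")
    rows = []
    for p in periods:
        for cid in sorted(assignments[p]):
            ph = (phenotypes or {}).get(cid, Phenotype.UNKNOWN)
            rows.append((p, cid, assignments[p][cid], Phenotype(ph).value))
    out = pd.DataFrame(rows, columns=["period", "cell_id", "cluster", "phenotype"])
    out.to_csv(path, index=False)


def read_assignments(path: str | Path) -> dict[int, dict[int, int]]:
    """Inverse of :func:`write_assignments` (phenotype column ignored)."""
    df = pd.read_csv(path)
    for col in ("period", "cell_id", "cluster"):
        if col not in df.columns:
            raise FormatError(f"missing required column(s): {col}")
    result: dict[int, dict[int, int]] = {}
    for row in df.itertuples(index=False):
        result.setdefault(int(row.period), {})[int(row.cell_id)] = int(row.cluster)
    return result
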