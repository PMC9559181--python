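"""Shared fixtures: small constructed tables and seeded synthetic colonies."""

import numpy as np
import pandas as pd
import pytest

from migpattern import (
    ColonyConfig,
    TrackTable,
    detect_divisions,
    generate_colony,
    unify_lineage,
)


def make_table(rows, n_slices=0, interval=15.0):
    """Build a TrackTable from (cell_id, slice, x, y[, phenotype]) tuples."""
    full = [r if len(r) == 5 else (*r, "UNKNOWN") for r in rows]
    df = pd.DataFrame(full, columns=["cell_id", "slice", "x", "y", "phenotype"])
    return TrackTable(df, interval, n_slices)


def straight_track(cell_id, start, stop, origin, step):
    """Records of a cell moving with a constant step vector."""
    origin = np.asarray(origin, float)
    step = np.asarray(step, float)
    return [
        (cell_id, s, *(origin + (s - start) * step)) for s in range(start, stop)
    ]


@pytest.fixture(scope="session")
def default_colony():
    """One default-parameter colony (28 founders, 97 slices, divisions)."""
    return generate_colony(ColonyConfig(), seed=11)


@pytest.fixture(scope="session")
def default_lineage(default_colony):
    table, _ = default_colony
    return unify_lineage(table, detect_divisions(table))


@pytest.fixture(scope="session")
def small_colony_config():
    """Division-free two-period colony used by the clustering-level tests."""
    return ColonyConfig(n_founders=32, n_slices=24, division_rate=0.0)
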