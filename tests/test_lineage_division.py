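"""Division detection and mother/daughter trajectory unification."""

import numpy as np
import pytest

from migpattern import (
    ColonyConfig,
    DivisionEvent,
    DomainError,
    IntegrityError,
    ParameterError,
    detect_divisions,
    generate_colony,
    pair_distance_series,
    step_sizes,
    unify_lineage,
)
from migpattern.lineage_division import render_lineage_tree

from conftest import make_table, straight_track


class TestPairDistanceSeries:
    def test_identical_tracks_give_zeros(self):
        t = make_table(straight_track(1, 0, 5, (0, 0), (1, 1)) + straight_track(2, 0, 5, (0, 0), (1, 1)))
        np.testing.assert_array_equal(pair_distance_series(t, 1, 2), np.zeros(5))

    def test_pythagorean_constant_offset(self):
        t = make_table([(1, 0, 0, 0), (1, 1, 0, 0), (2, 0, 3, 4), (2, 1, 3, 4)])
        np.testing.assert_allclose(pair_distance_series(t, 1, 2), [5.0, 5.0])

    def test_disjoint_tracks_rejected(self):
        t = make_table([(1, 0, 0, 0), (1, 1, 0, 0), (2, 2, 1, 1), (2, 3, 1, 1)], n_slices=4)
        with pytest.raises(DomainError):
            pair_distance_series(t, 1, 2)


class TestStepSizes:
    def test_stationary_cell_all_zeros(self):
        t = make_table([(1, s, 2.0, 3.0) for s in range(4)])
        np.testing.assert_array_equal(step_sizes(t, 1), np.zeros(3))

    def test_single_six_micron_step(self):
        t = make_table([(1, 0, 0, 0), (1, 1, 0, 6)])
        np.testing.assert_allclose(step_sizes(t, 1), [6.0])

    def test_too_short_track_rejected(self):
        t = make_table([(1, 0, 0, 0), (2, 0, 1, 1), (2, 1, 1, 1)])
        with pytest.raises(DomainError):
            step_sizes(t, 1)


class TestDetectDivisions:
    def test_distance_series_jump_marks_division(self):
        # two full-span tracks coincident for 3 slices then >= 10 um apart
        rows = []
        for s, d in enumerate([0.0, 0.0, 0.0, 12.0, 14.0]):
            rows.append((1, s, 0.0, 0.0))
            rows.append((2, s, d, 0.0))
        events = detect_divisions(make_table(rows))
        assert len(events) == 1
        assert events[0].division_slice == 3
        assert events[0].daughter_ids == (1, 2)

    def test_always_distant_pair_is_not_a_division(self):
        t = make_table(
            straight_track(1, 0, 6, (0, 0), (1, 0)) + straight_track(2, 0, 6, (50, 0), (1, 0))
        )
        assert detect_divisions(t) == []

    def test_thresholds_must_be_separated(self):
        t = make_table(straight_track(1, 0, 3, (0, 0), (1, 0)))
        with pytest.raises(ParameterError):
            detect_divisions(t, jump_threshold=5.0, proximity_threshold=6.0)

    def test_raw_mother_daughter_tracks(self):
        rows = straight_track(10, 0, 5, (0, 0), (0.5, 0))  # mother ends at slice 4
        last = np.array([2.0, 0.0])
        rows += straight_track(21, 5, 10, last + (0, 6), (0.5, 0))
        rows += straight_track(22, 5, 10, last - (0, 6), (0.5, 0))
        events = detect_divisions(make_table(rows))
        assert events == [DivisionEvent(10, (21, 22), 5)]

    def test_planted_events_recovered_on_colony(self):
        table, truth = generate_colony(ColonyConfig(), seed=4)
        found = {(e.mother_id, e.division_slice) for e in detect_divisions(table)}
        planted = {(e.mother_id, e.division_slice) for e in truth.division_events}
        assert found == planted


class TestUnifyLineage:
    def test_no_events_returns_input_tracks(self):
        t = make_table(
            straight_track(1, 0, 6, (0, 0), (1, 0)) + straight_track(2, 0, 6, (30, 0), (0, 1))
        )
        lineage = unify_lineage(t, [])
        assert lineage.cell_ids == [1, 2]
        np.testing.assert_allclose(lineage.trajectories[1], t.track(1)[1])

    def test_mother_prefix_copied_to_both_daughters(self):
        rows = straight_track(1, 0, 5, (0, 0), (1, 0))
        rows += straight_track(2, 5, 10, (4, 6), (1, 0))
        rows += straight_track(3, 5, 10, (4, -6), (1, 0))
        t = make_table(rows)
        lineage = unify_lineage(t, [DivisionEvent(1, (2, 3), 5)])
        assert lineage.cell_ids == [2, 3]
        for leaf in (2, 3):
            assert lineage.trajectories[leaf].shape == (10, 2)
        np.testing.assert_array_equal(
            lineage.trajectories[2][:5], lineage.trajectories[3][:5]
        )
        np.testing.assert_allclose(lineage.trajectories[2][:5], t.track(1)[1])

    def test_nested_division_shares_both_ancestral_prefixes(self):
        rows = straight_track(1, 0, 3, (0, 0), (1, 0))  # grandmother
        rows += straight_track(2, 3, 6, (3, 6), (1, 0))  # mother (daughter of 1)
        rows += straight_track(3, 3, 9, (3, -6), (1, 0))  # aunt, survives to the end
        rows += straight_track(4, 6, 9, (6, 12), (1, 0))  # granddaughters
        rows += straight_track(5, 6, 9, (6, 0), (1, 0))
        t = make_table(rows)
        events = [DivisionEvent(1, (2, 3), 3), DivisionEvent(2, (4, 5), 6)]
        lineage = unify_lineage(t, events)
        assert lineage.cell_ids == [3, 4, 5]
        np.testing.assert_array_equal(lineage.trajectories[4][:6], lineage.trajectories[5][:6])
        np.testing.assert_allclose(lineage.trajectories[4][:3], t.track(1)[1])
        np.testing.assert_allclose(lineage.trajectories[4][3:6], t.track(2)[1])
        assert lineage.parent[4] == 2 and lineage.parent[2] == 1

    def test_unknown_cell_in_event_rejected(self):
        t = make_table(straight_track(1, 0, 5, (0, 0), (1, 0)))
        with pytest.raises(IntegrityError):
            unify_lineage(t, [DivisionEvent(1, (8, 9), 2)])

    def test_unification_conserves_observed_points(self, default_colony, default_lineage):
        table, _ = default_colony
        lineage = default_lineage
        stacked = lineage.positions()
        for row in table.df.itertuples(index=False):
            at_slice = stacked[:, row.slice, :]
            hit = np.isclose(at_slice[:, 0], row.x) & np.isclose(at_slice[:, 1], row.y)
            assert hit.any(), f"record of cell {row.cell_id} at slice {row.slice} lost"

    def test_daughters_coincide_exactly_before_division(self, default_colony, default_lineage):
        _, truth = default_colony
        lineage = default_lineage
        leaves = set(lineage.cell_ids)
        for ev in truth.division_events:
            d1, d2 = ev.daughter_ids
            if d1 in leaves and d2 in leaves:
                pre1 = lineage.trajectories[d1][: ev.division_slice]
                pre2 = lineage.trajectories[d2][: ev.division_slice]
                np.testing.assert_array_equal(pre1, pre2)

    def test_leaf_count_matches_last_slice(self, default_colony, default_lineage):
        table, _ = default_colony
        last = table.df[table.df["slice"] == table.n_slices - 1]
        assert default_lineage.n_cells == len(last)

    def test_tree_rendering_lists_every_cell(self, default_lineage):
        listed = {
            line.strip() for line in render_lineage_tree(default_lineage).splitlines()
        }
        for cid in default_lineage.cell_ids:
            assert f"cell {cid}" in listed


def test_recovery_is_exact_across_seeds():
    """Raw-mode detection recovers planted divisions perfectly (a few seeds;
    the 20-seed version runs in the acceptance suite)."""
    for seed in range(3):
        table, truth = generate_colony(ColonyConfig(), seed=seed)
        found = {(e.mother_id, frozenset(e.daughter_ids), e.division_slice) for e in detect_divisions(table)}
        planted = {(e.mother_id, frozenset(e.daughter_ids), e.division_slice) for e in truth.division_events}
        assert found == planted
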