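"""Site choice: candidates, direction memory, attraction, collisions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tubecast as tc
from tubecast.arena import N4, N8
from tubecast.builder import (_block_window, candidate_d, direction_sum,
                              evaluate_candidates)
from tubecast.stigmergy import candidate_crowdedness


class TestCandidateSet:
    def test_fresh_arena_ring_matches_brute_force(self):
        params = tc.SimParams(group_size=50, width=40, height=30,
                              nest_area=13, stop_count=10)
        state = params.make_state()
        got = tc.candidate_set(state)
        # oracle: exhaustive scan of the whole grid
        expected = set()
        for r in range(30):
            for c in range(40):
                if state.arena.state[r, c] != tc.EMPTY:
                    continue
                if any(state.arena.in_bounds(r + dr, c + dc)
                       and state.arena.state[r + dr, c + dc] != tc.EMPTY
                       for dr, dc in N4):
                    expected.add((r, c))
        assert got == expected

    def test_crowded_cells_are_excluded(self, tube_state):
        state, cp = tube_state
        state.crowd.w[10, 12] = 0.9  # tip cell fully crowded
        s = tc.candidate_set(state)
        # every candidate whose only built neighbour is the tip is gone
        assert (10, 13) not in s
        assert (9, 13) not in s
        # candidates adjacent to the uncrowded origin cell remain
        assert (9, 11) in s

    def test_blocked_window_cells_never_candidates(self, tube_state):
        state, cp = tube_state
        state.arena.blocked[:] = True
        state.cand_mask[:] = False
        assert tc.candidate_set(state) == set()


class TestDirectionFactor:
    def test_straight_continuation_is_one(self, tube_state):
        state, cp = tube_state
        assert tc.direction_factor((10, 13), (10, 12), state, cp) == \
            pytest.approx(1.0)

    def test_pointing_back_to_origin_is_zero(self, tube_state):
        state, cp = tube_state
        assert tc.direction_factor((10, 11), (10, 12), state, cp) == \
            pytest.approx(0.0)

    def test_perpendicular_step_is_half(self, tube_state):
        state, cp = tube_state
        assert tc.direction_factor((9, 12), (10, 12), state, cp) == \
            pytest.approx(0.5)

    def test_via_at_own_origin_uses_outward_nest_direction(self, tube_state):
        state, cp = tube_state
        # (10, 11) is its own origin; nest centre is (10, 10), so outward is
        # +col and the eastward diagonal candidates score cos(45 deg)
        v = tc.direction_factor((9, 12), (10, 11), state, cp)
        assert v == pytest.approx(0.5 + 0.5 * math.cos(math.pi / 4))

    def test_leaving_edge_band_returns_empirical_constant(self):
        arena = tc.init_arena(width=31, height=31, nest_area=1, group_size=50)
        state = tc.BuildState.from_arena(arena)
        cp = tc.ChoiceParams()
        # walk a tube from the nest at (15, 15) to the wall band (band = 4)
        for c in range(16, 28):
            tc.build(state, (15, c), cp)
        via = (15, 27)  # inside the band (col >= 27)
        assert state.band_mask[via]
        inward = (15, 26)
        assert not state.band_mask[inward]
        got = tc.direction_factor(inward, via, state, cp)
        assert got == 0.0007274

    def test_direction_sum_is_one_with_only_nest_neighbours(self):
        params = tc.SimParams(group_size=50, width=21, height=21, nest_area=1,
                              stop_count=10)
        state = params.make_state()
        assert direction_sum((10, 11), state, params.choice_params) == 1.0

    def test_direction_sum_adds_over_built_neighbours(self, tube_state):
        state, cp = tube_state
        expected = sum(
            tc.direction_factor((9, 12), via, state, cp)
            for via in [(10, 11), (10, 12)])
        assert direction_sum((9, 12), state, cp) == pytest.approx(expected)


class TestAttraction:
    def test_hand_computed_value(self, tube_state):
        # c=0.3, k=2, b=1/360, d=36, v=1, x=2 -> (0.3 + 2 - 0.1)^2 = 4.84
        state, _ = tube_state
        cp = tc.ChoiceParams(x=2.0)
        state.pher.c[10, 12] = 0.3
        state.arena.k_field[10, 13] = 2.0
        state.dstore[10, 12] = 35.0  # candidate d = 36
        assert tc.attraction((10, 13), state, cp) == pytest.approx(4.84)

    def test_unit_base_gives_direction_sum(self, tube_state):
        state, _ = tube_state
        cp = tc.ChoiceParams(x=5.0, b=1e-9)
        state.pher.c[:] = 0.0
        # c=0, k=1, b~0 -> base ~1 -> A ~ v for any x
        a = tc.attraction((10, 13), state, cp)
        assert a == pytest.approx(direction_sum((10, 13), state, cp), rel=1e-6)

    def test_negative_base_clamps_to_zero(self, tube_state):
        state, _ = tube_state
        cp = tc.ChoiceParams(x=2.5, b=10.0)  # b*d >> c + k
        assert tc.attraction((10, 13), state, cp) == 0.0

    def test_zero_direction_sum_kills_attraction(self, tube_state):
        state, _ = tube_state
        cp = tc.ChoiceParams(x=2.0)
        # candidate whose only built neighbour points straight back: v = 0
        state.arena.state[10, 11] = tc.EMPTY  # detach origin cell
        state.dstore[10, 11] = np.inf
        a = tc.attraction((10, 11), state, cp)
        assert a == 0.0


class TestChoiceDistribution:
    def test_equal_attractions_split_evenly(self):
        assert tc.choice_distribution([2.0, 2.0]) == pytest.approx([0.5, 0.5])

    def test_normalisation(self):
        assert tc.choice_distribution([1.0, 3.0]) == pytest.approx([0.25, 0.75])

    def test_all_zero_falls_back_to_uniform(self):
        assert tc.choice_distribution([0.0, 0.0, 0.0, 0.0]) == \
            pytest.approx([0.25] * 4)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            tc.choice_distribution([])

    @given(st.lists(st.floats(0.0, 1e6), min_size=1, max_size=30))
    def test_sums_to_one(self, attractions):
        p = tc.choice_distribution(attractions)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()


@given(
    c=st.floats(0.0, 3.0), k=st.sampled_from([1.0, 2.0]),
    d=st.floats(1.0, 700.0), x=st.floats(0.0, 3.0),
    dc=st.floats(0.01, 0.5), dk=st.floats(0.01, 1.0), dd=st.floats(1.0, 20.0),
)
def test_attraction_base_monotonicity(c, k, d, x, dc, dk, dd):
    """A rises with pheromone and preference, falls with distance (fixed v)."""
    def a(ci, ki, di):
        base = ci + ki - di / 360.0
        return max(0.0, base) ** x if base > 0 else 0.0

    assert a(c + dc, k, d) >= a(c, k, d)
    assert a(c, k + dk, d) >= a(c, k, d)
    assert a(c, k, d + dd) <= a(c, k, d)


def test_x_zero_gives_uniform_choice_over_positive_base(midrun_state):
    cp = tc.ChoiceParams(x=0.0)
    cells = sorted(tc.candidate_set(midrun_state))
    attr = [tc.attraction(cell, midrun_state, cp) for cell in cells]
    vs = [direction_sum(cell, midrun_state, cp) for cell in cells]
    for a, v in zip(attr, vs):
        assert a == pytest.approx(v)  # base^0 = 1 wherever base > 0


class TestBuild:
    def test_first_build_near_nest_starts_new_tube(self):
        params = tc.SimParams(group_size=50, width=21, height=21, nest_area=1,
                              stop_count=10)
        state = params.make_state()
        tc.build(state, (10, 11), params.choice_params)
        assert state.origin_r[10, 11] == 10.0
        assert state.origin_c[10, 11] == 11.0
        assert state.arena.state[10, 11] == tc.BUILT
        assert state.pher.c[10, 11] == pytest.approx(0.3)
        assert state.built_count == 1

    def test_extension_inherits_origin(self, tube_state):
        state, cp = tube_state
        tc.build(state, (10, 13), cp)
        assert state.origin_r[10, 13] == 10.0
        assert state.origin_c[10, 13] == 11.0

    def test_junction_of_two_origins_takes_midpoint(self):
        params = tc.SimParams(group_size=50, width=21, height=21, nest_area=1,
                              stop_count=30)
        state = params.make_state()
        cp = params.choice_params
        # two tubes east and north of the nest, origins (10,11) and (9,10)
        tc.build(state, (10, 11), cp)
        tc.build(state, (9, 10), cp)
        # (9, 11) touches both tubes (8-adjacency) but not the nest ring?
        # it IS diagonal to the nest, but not 4-adjacent, so it inherits
        tc.build(state, (9, 11), cp)
        assert state.origin_r[9, 11] == pytest.approx((10.0 + 9.0) / 2)
        assert state.origin_c[9, 11] == pytest.approx((11.0 + 10.0) / 2)

    def test_wall_contact_starts_new_tube(self):
        params = tc.SimParams(group_size=50, width=21, height=21, nest_area=1,
                              stop_count=30)
        state = params.make_state()
        cp = params.choice_params
        for c in range(11, 20):
            tc.build(state, (10, c), cp)
        tc.build(state, (10, 20), cp)  # touches the east wall
        assert state.origin_r[10, 20] == 10.0
        assert state.origin_c[10, 20] == 20.0

    def test_build_inherits_perceived_fields_plus_increment(self, tube_state):
        state, cp = tube_state
        state.pher.c[10, 12] = 1.0
        state.crowd.w[10, 12] = 0.4
        tc.build(state, (10, 13), cp)
        assert state.pher.c[10, 13] == pytest.approx(1.0 + 0.3)
        assert state.crowd.w[10, 13] == pytest.approx(0.4 + 0.3)

    def test_build_on_occupied_or_blocked_is_an_error(self, tube_state):
        state, cp = tube_state
        with pytest.raises(ValueError):
            tc.build(state, (10, 12), cp)
        state.arena.blocked[5, 5] = True
        with pytest.raises(ValueError):
            tc.build(state, (5, 5), cp)


class TestCollision:
    def _state(self, side=40):
        params = tc.SimParams(group_size=50, width=side, height=side,
                              nest_area=1, stop_count=500)
        return params.make_state(), params.choice_params

    def test_far_detour_counts_as_different_tubes(self):
        state, cp = self._state()
        r0 = 20
        state.arena.state[r0, 21] = tc.BUILT
        state.dstore[r0, 21] = 1.0
        state.arena.state[r0, 22] = tc.BUILT
        state.dstore[r0, 22] = 41.0  # came back after a long detour
        tc.detect_collision(state, (r0, 22), cp)
        assert state.contact[r0, 21] and state.contact[r0, 22]

    def test_single_tube_corner_is_not_a_collision(self):
        state, cp = self._state()
        # L-shaped tube built normally: |d| differences stay <= 2
        for c in range(21, 30):
            tc.build(state, (20, c), cp)
        for r in range(21, 28):
            tc.build(state, (r, 29), cp)
        assert not state.contact.any()
        assert not state.arena.blocked.any()

    def test_blocking_needs_eight_contact_cells(self):
        state, cp = self._state()
        # plant 7 contact cells near the last build: no block yet
        state.contact[20, 10:17] = True
        state.arena.state[20, 18] = tc.BUILT
        state.dstore[20, 18] = 1.0
        state.arena.state[20, 17] = tc.BUILT
        state.dstore[20, 17] = 50.0
        blocked = tc.detect_collision(state, (20, 17), cp)
        # window centred on (20,17) covers cols 14..21: contacts inside are
        # (20,14..16) + the new pair = 5 < 8
        assert not blocked
        state.contact[19, 14:17] = True  # three more inside the window
        blocked = tc.detect_collision(state, (20, 17), cp)
        assert blocked
        win = _block_window(state.arena.shape, (20, 17), 8)
        assert state.arena.blocked[win].all()
        assert not state.cand_mask[win].any()

    def test_window_geometry(self):
        win = _block_window((40, 40), (20, 17), 8)
        assert (win[0].stop - win[0].start, win[1].stop - win[1].start) == (8, 8)
        assert win[0].start == 17 and win[1].start == 14


class TestVectorisedKernel:
    def test_matches_scalar_reference_midrun(self, midrun_state):
        state = midrun_state
        cp = tc.ChoiceParams(x=2.0)
        rows, cols, attr, keep = evaluate_candidates(state, cp)
        cells = list(zip(rows.tolist(), cols.tolist()))
        assert set(cells) == tc.candidate_set(state, apply_crowd_filter=False)
        for (cell, a, k) in zip(cells, attr, keep):
            assert a == pytest.approx(tc.attraction(cell, state, cp), abs=1e-10)
            crowded = (candidate_crowdedness(state.crowd, cell, state.arena)
                       >= state.crowd.threshold)
            assert k == (not crowded)

    def test_matches_scalar_on_edge_band_structure(self):
        arena = tc.init_arena(width=31, height=31, nest_area=1, group_size=50)
        state = tc.BuildState.from_arena(arena)
        cp = tc.ChoiceParams(x=3.0)
        for c in range(16, 29):
            tc.build(state, (15, c), cp)
        for r in range(16, 20):
            tc.build(state, (r, 28), cp)  # runs inside the band
        rows, cols, attr, _ = evaluate_candidates(state, cp)
        for r, c, a in zip(rows.tolist(), cols.tolist(), attr):
            assert a == pytest.approx(tc.attraction((r, c), state, cp),
                                      abs=1e-10)
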