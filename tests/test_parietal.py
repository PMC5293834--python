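"""Cue sensing, ECD/EGCD coding, movement cells, routes, conjunctive cells."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from refnav.config import SensoryConfig
from refnav.hippocampus import CognitiveMap, Landmark
from refnav.neural_coding import (
    CellPopulation,
    encode_population,
    gaussian_tuning,
    wrap_angle,
)
from refnav.parietal import (
    CueVector,
    MovementCellActivity,
    RouteMemory,
    conjunctive_response,
    ecd_population,
    ecd_raw,
    egcd_cue_following,
    egcd_modulate,
    movement_cells,
    sense_cues,
    sequential_step,
)
from refnav.retrosplenial import HeadDirectionState

PARAMS = SensoryConfig()


def cue_at(x, y, cid="c"):
    return SimpleNamespace(id=cid, position=(x, y))


class TestSenseCues:
    @pytest.mark.parametrize(
        "heading, cue_xy, expected",
        [
            (90.0, (0, 5), (5.0, 0.0)),         # dead ahead
            (0.0, (3, 4), (5.0, 53.13010235)),  # 3-4-5 triangle
            (180.0, (3, 4), (5.0, -126.86989765)),
        ],
    )
    def test_distance_and_direction(self, heading, cue_xy, expected):
        [cv] = sense_cues((0, 0), heading, [cue_at(*cue_xy)], PARAMS)
        assert cv.distance == pytest.approx(expected[0])
        assert cv.egocentric_direction == pytest.approx(expected[1])

    def test_cue_at_agent_position_rejected(self):
        with pytest.raises(ValueError):
            sense_cues((1, 1), 0.0, [cue_at(1, 1)], PARAMS)

    def test_field_of_view_excludes_rear_cues(self):
        params = SensoryConfig(field_of_view=180.0)
        out = sense_cues((0, 0), 0.0, [cue_at(-5, 0.1), cue_at(5, 0)], params)
        assert [cv.cue_id for cv in out] == ["c"]


class TestECD:
    def test_distance_to_activation_law(self):
        raw = ecd_raw([CueVector("c", 3.0, 40.0)], PARAMS)
        assert raw[40] == pytest.approx(1.0)  # D/d = 3/3
        raw6 = ecd_raw([CueVector("c", 6.0, 40.0)], PARAMS)
        assert raw6[40] == pytest.approx(0.5)  # D/d = 3/6

    def test_mirror_cues_symmetric_about_zero(self):
        pop = ecd_population(
            [CueVector("a", 4.0, 40.0), CueVector("b", 4.0, -40.0)], PARAMS, noise=None
        )
        # unit preferring +x matches unit preferring -x
        for x in (10, 40, 90, 150):
            assert pop.activities[x] == pytest.approx(pop.activities[360 - x], rel=1e-9)

    def test_no_cues_flagged_degenerate(self):
        pop = ecd_population([], PARAMS, noise=None)
        assert pop.is_degenerate
        assert np.all(pop.activities == 0.0)


def brute_force_egcd(ecd, egd, sigma_w=80.0):
    n = len(ecd)
    out = np.zeros(n)
    for i in range(n):
        total = 0.0
        for m in range(n):
            w = gaussian_tuning(ecd.preferred_angles[i], egd.preferred_angles[m], sigma_w)
            if egd.activities[m] > 0.5:
                total += egd.activities[m] * w
            else:
                total += egd.activities[m] * (w - 1.0)
        out[i] = max(ecd.activities[i] * total, 0.0)
    peak = out.max()
    return out / peak if peak > 0 else out


class TestEGCDModulation:
    def test_matches_brute_force_double_loop(self, rng):
        n = 48  # smaller population keeps the O(n^2) oracle fast
        prefs = np.arange(n) * 360.0 / n
        for _ in range(5):
            ecd = CellPopulation(prefs, rng.uniform(0, 1, n), 10.0)
            egd = CellPopulation(prefs, rng.uniform(0, 1, n), 10.0)
            fast = egcd_modulate(ecd, egd)
            slow = brute_force_egcd(ecd, egd)
            assert np.allclose(fast.activities, slow, atol=1e-9)

    def test_goal_closest_cue_enhanced(self):
        ecd = ecd_population(
            [CueVector("far", 4.0, -90.0), CueVector("near", 4.0, 10.0)], PARAMS, noise=None
        )
        egd = encode_population(0.0, 10.0, 360)  # goal dead ahead
        egcd = egcd_modulate(ecd, egd)
        peak_angle = wrap_angle(egcd.preferred_angles[int(np.argmax(egcd.activities))])
        assert abs(peak_angle - 10.0) <= 5.0

    def test_goal_closest_cue_wins_over_geometry_grid(self):
        for goal in (-120.0, -40.0, 0.0, 60.0, 170.0):
            for sep in (60.0, 120.0):
                a, b = goal - sep / 2 - 20, goal + sep / 2 - 20  # b is closer to goal
                ecd = ecd_population(
                    [CueVector("a", 4.0, wrap_angle(a)), CueVector("b", 4.0, wrap_angle(b))],
                    PARAMS,
                    noise=None,
                )
                egd = encode_population(goal % 360.0, 10.0, 360)
                egcd = egcd_modulate(ecd, egd)
                peak = wrap_angle(egcd.preferred_angles[int(np.argmax(egcd.activities))])
                assert abs(wrap_angle(peak - b)) < abs(wrap_angle(peak - a))

    def test_weak_goal_signal_inhibits_everything(self):
        ecd = ecd_population([CueVector("c", 4.0, 30.0)], PARAMS, noise=None)
        egd = CellPopulation(ecd.preferred_angles.copy(), np.full(360, 0.4), 10.0)
        egcd = egcd_modulate(ecd, egd)
        assert np.all(egcd.activities == 0.0)

    def test_size_mismatch_rejected(self):
        ecd = encode_population(0.0, 10.0, 360)
        egd = encode_population(0.0, 10.0, 180)
        with pytest.raises(ValueError):
            egcd_modulate(ecd, egd)


class TestCueFollowing:
    def test_equals_pure_encoding(self):
        bump = egcd_cue_following(CueVector("g", 99.0, -120.0), noise=None)
        expected = encode_population(-120.0 % 360.0, 10.0, 360)
        assert np.allclose(bump.activities, expected.activities)

    def test_peak_straight_ahead(self):
        bump = egcd_cue_following(CueVector("g", 1.0, 0.0), noise=None)
        assert int(np.argmax(bump.activities)) == 0


class TestMovementCells:
    def test_uniform_band_widths(self):
        pop = CellPopulation(np.arange(360.0), np.ones(360), 10.0)
        mv = movement_cells(pop)
        assert mv.mv_left == pytest.approx(mv.mv_right) == pytest.approx(180.0)
        assert mv.mv_forward == pytest.approx(109.0)  # 109/180 of a hemifield

    def test_centred_bump_nearly_balanced(self):
        pop = encode_population(0.0, 10.0, 360)
        mv = movement_cells(pop)
        # the 0-degree unit itself sits in the left band; asymmetry is at most that one unit
        assert abs(mv.mv_left - mv.mv_right) <= 1.0 + 1e-9
        assert mv.mv_forward > 0.9 * (mv.mv_left + mv.mv_right) / 2

    def test_left_bump_drives_left_cell(self):
        pop = encode_population(-120.0 % 360.0, 10.0, 360)
        mv = movement_cells(pop)
        assert mv.mv_left > mv.mv_right

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            movement_cells(encode_population(0.0, 10.0, 90))

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            MovementCellActivity(-0.1, 0.0, 0.0)


def junction_map():
    cmap = CognitiveMap()
    cmap.add_landmark(Landmark("J", (0.0, 0.0), is_choice_point=True))
    cmap.add_landmark(Landmark("E", (0.0, 10.0)))
    cmap.add_edge("J", "E")
    return cmap


class TestSequentialStep:
    def test_far_from_landmark_goes_straight(self):
        route = RouteMemory("sequential_egocentric", [("J", -54.0)])
        override = sequential_step(route, (5.0, 5.0), 90.0, junction_map(), 0.5)
        assert override.turn_remaining is None
        assert override.mv.as_tuple() == (0.0, 1.0, 0.0)

    def test_turn_triggered_at_choice_point(self):
        route = RouteMemory("sequential_egocentric", [("J", -54.0)])
        override = sequential_step(route, (0.1, 0.0), 90.0, junction_map(), 0.5)
        assert override.turn_remaining == pytest.approx(-54.0)
        assert override.mv.as_tuple() == (1.0, 0.0, 0.0)  # left saturating drive

    def test_turn_completes_and_advances_progress(self):
        route = RouteMemory("sequential_egocentric", [("J", -54.0)])
        sequential_step(route, (0.1, 0.0), 90.0, junction_map(), 0.5)
        override = sequential_step(route, (0.1, 0.0), 36.5, junction_map(), 0.5)
        assert override.turn_remaining is None
        assert route.progress_index == 1

    def test_exhausted_route_returns_none(self):
        route = RouteMemory("sequential_egocentric", [], progress_index=0)
        assert sequential_step(route, (9.0, 9.0), 0.0, junction_map(), 0.5) is None

    def test_wrong_kind_rejected(self):
        route = RouteMemory("cue_following", [("J", 0.0)])
        with pytest.raises(ValueError):
            sequential_step(route, (0, 0), 0.0, junction_map(), 0.5)


class TestConjunctiveCells:
    def test_peak_response_at_preferred_pair(self):
        hd = HeadDirectionState.from_heading(310.0, noise=None)
        ecd = ecd_population([CueVector("c", 3.0, 150.0)], PARAMS, noise=None)
        assert conjunctive_response(310.0, 150.0, hd, ecd) == pytest.approx(1.0)

    def test_orthogonal_heading_suppresses(self):
        hd = HeadDirectionState.from_heading(40.0, noise=None)
        ecd = ecd_population([CueVector("c", 3.0, 150.0)], PARAMS, noise=None)
        assert conjunctive_response(310.0, 150.0, hd, ecd) == pytest.approx(math.exp(-81.0), abs=1e-12)

    def test_response_factorizes(self):
        """response(hd, cue) = f(hd) * g(cue) exactly, noise off."""
        headings = [0.0, 95.0, 310.0]
        cue_angles = [-90.0, 30.0, 150.0]
        f = {}
        g = {}
        grid = {}
        for h in headings:
            hd = HeadDirectionState.from_heading(h, noise=None)
            f[h] = hd.population.value_at(310.0)
            for c in cue_angles:
                ecd = ecd_population([CueVector("c", 3.0, c)], PARAMS, noise=None)
                g[c] = ecd.value_at(150.0)
                grid[(h, c)] = conjunctive_response(310.0, 150.0, hd, ecd)
        for (h, c), resp in grid.items():
            assert resp == pytest.approx(f[h] * g[c], rel=1e-12)

    def test_no_cue_means_no_response(self):
        hd = HeadDirectionState.from_heading(310.0, noise=None)
        ecd = ecd_population([], PARAMS, noise=None)
        assert conjunctive_response(310.0, 150.0, hd, ecd) == 0.0
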