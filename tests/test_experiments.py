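"""End-to-end behaviour of the simulation loop and the three experiments."""

import numpy as np
import pytest

from refnav.config import blinking_config, starmaze_config, vista_config
from refnav.environments import (
    build_blinking_light_arena,
    build_starmaze,
    build_vista_world,
    starmaze_pose,
)
from refnav.experiments import (
    STRATEGIES_STARMAZE,
    Simulation,
    TrialLog,
    classify_starmaze_trial,
    mean_confidence_traces,
    replace_start,
    run_blinking_light,
    run_starmaze,
    run_vista,
    run_vista_trial,
    strategy_contribution,
    train_starmaze_sequence,
)
from refnav.motor import step_kinematics, velocity_command
from refnav.parietal import RouteMemory, ecd_population, movement_cells, sense_cues


def frozen_starmaze_trial(env, trained, config, strategy, start="a5", max_steps=2000, seed=0):
    """Run a probe with the arbitration frozen to one strategy."""
    start_pos, start_heading = starmaze_pose(env, start)
    route = RouteMemory("sequential_egocentric", list(trained.sequence))
    sim = Simulation(
        replace_start(env, start_pos, start_heading),
        config,
        STRATEGIES_STARMAZE,
        np.random.default_rng(seed),
        goal_position=env.map.position("a7"),
        goal_landmark="a7",
        initial_strategy=strategy,
        route_memory=route,
    )
    goal = env.map.position("a7")
    a1 = env.map.position("a1")
    for _ in range(max_steps):
        sim.step(arbitrate=False)
        if np.linalg.norm(sim.agent.position - goal) <= config.capture_radius:
            sim.log.outcome["terminal"] = "a7"
            break
        if (
            strategy == "route_sequential"
            and start != "a1"
            and np.linalg.norm(sim.agent.position - a1) <= config.capture_radius
        ):
            sim.log.outcome["terminal"] = "a1"
            break
    sim.log.outcome["capture_radius"] = config.capture_radius
    return sim


class TestBlinkingLight:
    def test_cue_dead_ahead_drives_straight_to_capture(self):
        """Single active cue straight ahead, noise off: no turning, forward
        motion, capture well within 200 steps."""
        cfg = blinking_config()
        cfg.neural.noise_mode = "off"
        rng = np.random.default_rng(0)
        env = build_blinking_light_arena(rng=rng)
        for c in env.cues:
            c.active = c.position[0] == pytest.approx(5.0) and abs(c.position[1]) < 1e-9
        assert len(env.active_cues) == 1
        from refnav.motor import AgentState

        agent = AgentState(np.zeros(2), 0.0)
        captured = False
        for _ in range(200):
            cues = sense_cues(agent.position, agent.heading, env.active_cues, cfg.sensory)
            ecd = ecd_population(cues, cfg.sensory, noise=None)
            agent = step_kinematics(agent, velocity_command(movement_cells(ecd)), env.walls)
            assert abs(agent.heading) < 1.0
            if np.linalg.norm(agent.position - np.array([5.0, 0.0])) <= cfg.capture_radius:
                captured = True
                break
        assert captured

    def test_run_visits_many_cues_with_straight_approaches(self):
        log, recordings = run_blinking_light(blinking_config(), seed=3, n_steps=3000)
        assert log.outcome["distinct_cues_visited"] >= 20
        headings = np.array([r["heading"] for r in log.records])
        dh = np.abs((np.diff(headings) + 180) % 360 - 180)
        assert np.mean(dh < 1.0) > 0.5  # mostly straight segments between switches

    def test_exactly_one_active_cue_each_step(self):
        cfg = blinking_config()
        rng = np.random.default_rng(1)
        env = build_blinking_light_arena(rng=rng)
        from refnav.environments import advance_blinking_cue

        for _ in range(500):
            assert len(env.active_cues) == 1
            advance_blinking_cue(env, env.active_cues[0].position, 0.5, rng)

    def test_conjunctive_recordings_present(self):
        _, recordings = run_blinking_light(blinking_config(), seed=5, n_steps=200)
        df = recordings["cells"]
        assert "conj_310_150" in df.columns
        assert df["conj_310_150"].between(0, 1).all()


@pytest.fixture(scope="module")
def trained_starmaze():
    env = build_starmaze()
    return env, train_starmaze_sequence(env)


class TestStarmaze:
    @pytest.fixture()
    def env_and_route(self, trained_starmaze):
        return trained_starmaze

    def test_training_replay_reaches_goal(self, env_and_route):
        """Noise-free replay of the trained sequence from the training start
        lands in the goal alley."""
        env, trained = env_and_route
        cfg = starmaze_config()
        cfg.neural.noise_mode = "off"
        sim = frozen_starmaze_trial(env, trained, cfg, "route_sequential", start="a1")
        assert sim.log.outcome.get("terminal") == "a7"

    def test_probe_replay_terminates_in_alley_one(self, env_and_route):
        env, trained = env_and_route
        for seed in range(3):
            sim = frozen_starmaze_trial(
                env, trained, starmaze_config(), "route_sequential", seed=seed
            )
            assert sim.log.outcome.get("terminal") == "a1"
            assert classify_starmaze_trial(sim.log, env) == "egocentric"

    def test_frozen_allocentric_reaches_goal_without_ring_crossing(self, env_and_route):
        env, trained = env_and_route
        for seed in range(3):
            sim = frozen_starmaze_trial(env, trained, starmaze_config(), "allocentric", seed=seed)
            assert sim.log.outcome.get("terminal") == "a7"
            assert classify_starmaze_trial(sim.log, env) == "allocentric"

    def test_classifier_on_synthetic_trajectories(self, env_and_route):
        env, _ = env_and_route

        def log_through(points, terminal):
            log = TrialLog(records=[{"t": i, "x": x, "y": y} for i, (x, y) in enumerate(points)])
            log.outcome = {"terminal": terminal, "capture_radius": 0.5}
            return log

        a7 = tuple(env.map.position("a7"))
        a1 = tuple(env.map.position("a1"))
        sentinel = tuple(env.metadata["mixed_sentinel_xy"])
        assert classify_starmaze_trial(log_through([(5, -8), a7], "a7"), env) == "allocentric"
        assert classify_starmaze_trial(log_through([(5, -8), a1], "a1"), env) == "egocentric"
        assert classify_starmaze_trial(log_through([(5, -8), sentinel, a7], "a7"), env) == "mixed"
        no_terminal = log_through([(5, -8)], None)
        no_terminal.outcome = {"capture_radius": 0.5}
        assert classify_starmaze_trial(no_terminal, env) == "timeout"

    def test_batch_reproducible_and_consistent(self):
        r1 = run_starmaze(starmaze_config(), n_trials=3, seed=77)
        r2 = run_starmaze(starmaze_config(), n_trials=3, seed=77)
        for t1, t2 in zip(r1.trials, r2.trials):
            assert t1.records == t2.records
            assert t1.outcome == t2.outcome
        assert r1.labels == r2.labels
        assert sum(r1.counts.values()) == 3

    def test_confidence_traces_separate_by_category(self):
        result = run_starmaze(starmaze_config(), n_trials=16, seed=4)
        finals = {"allocentric": [], "egocentric": []}
        for t in result.trials:
            label = t.outcome["label"]
            if label in finals:
                last = t.records[-1]
                finals[label].append(last["conf_allocentric"] - last["conf_route_sequential"])
        if finals["allocentric"]:
            assert np.mean(finals["allocentric"]) > 0
        if finals["egocentric"]:
            assert np.mean(finals["egocentric"]) < 0
        traces = mean_confidence_traces(result)
        for frame in traces.values():
            assert set(frame.columns) == set(STRATEGIES_STARMAZE)


class TestVista:
    def test_route_centric_alone_reaches_every_goal(self):
        res = run_vista(vista_config(), n_trials=4, seed=9, strategies=("route_cue",))
        assert res.counts["reached"] == 4
        for contrib in res.extras["contributions"]:
            assert contrib["route_cue"] == pytest.approx(100.0)

    def test_blocking_an_unused_corridor_leaves_trajectory_unchanged(self):
        cfg = vista_config()
        logs = []
        for blocked in (None, [("1", "6")]):
            env = build_vista_world(blocked=blocked)
            rng = np.random.default_rng(123)
            logs.append(run_vista_trial(env, cfg, rng, goal_region="5"))
        assert logs[0].records == logs[1].records

    def test_contribution_metric_hand_worked(self, vista):
        """Six poses walking from the start centroid to a goal in the next
        region; route lengths via the nearest landmark are hand-computed."""
        positions = [(3, 3), (5, 3), (7.5, 3), (9, 3), (10, 3), (10.8, 3)]
        strategies = ["route_cue", "route_cue", "egocentric", "egocentric", "allocentric", "route_cue"]
        log = TrialLog(
            records=[
                {"t": i, "x": x, "y": y, "strategy": s}
                for i, ((x, y), s) in enumerate(zip(positions, strategies))
            ]
        )
        log.outcome = {"goal_region": "5"}
        # route lengths: 8, 10, 3.5, 2, 1, 0.2 -> progress at steps 2,3,4,5
        contrib = strategy_contribution(log, vista)
        assert contrib["egocentric"] == pytest.approx(50.0)
        assert contrib["allocentric"] == pytest.approx(25.0)
        assert contrib["route_cue"] == pytest.approx(25.0)

    def test_single_strategy_trial_contributes_everything(self):
        res = run_vista(vista_config(), n_trials=1, seed=13, strategies=("route_cue",))
        contrib = res.extras["contributions"][0]
        assert contrib["route_cue"] == pytest.approx(100.0)
        assert sum(contrib.values()) == pytest.approx(100.0)

    def test_contributions_sum_to_hundred(self):
        res = run_vista(vista_config(), n_trials=3, seed=21)
        for contrib in res.extras["contributions"]:
            assert sum(contrib.values()) == pytest.approx(100.0)

    def test_batch_reproducible(self):
        r1 = run_vista(vista_config(), n_trials=2, seed=31)
        r2 = run_vista(vista_config(), n_trials=2, seed=31)
        for t1, t2 in zip(r1.trials, r2.trials):
            assert t1.records == t2.records


class TestWheelInvariant:
    def test_velocities_never_negative_across_a_run(self):
        res = run_starmaze(starmaze_config(), n_trials=2, seed=55)
        for t in res.trials:
            for rec in t.records:
                assert rec["v_left"] >= 0.0 and rec["v_right"] >= 0.0
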