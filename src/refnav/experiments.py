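"""Experiment runners: the per-step loop and the three studies.

The :class:`Simulation` object wires the brain modules together for one
trial: sense the cues, locate the active place cell and the allocentric
goal direction (hippocampus), transform to the egocentric goal direction
and update the strategy confidences (retrosplenial), convert the active
strategy into movement-cell drive (parietal), and advance the
differential-drive agent (motor).  On top of it sit the three
experiment runners:

* :func:`run_blinking_light` — egocentric cue chasing with conjunctive-
  cell recordings (arbitration disabled);
* :func:`run_starmaze` — 130-style probe trials arbitrating between the
  allocentric and the sequential-egocentric route strategy, classified
  by terminal alley;
* :func:`run_vista` — goal seeking across eight corridor-linked regions
  with the full three-strategy arbitration and the strategy-
  contribution metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .config import ModelConfig, blinking_config, starmaze_config, vista_config
from .environments import (
    Environment,
    advance_blinking_cue,
    build_blinking_light_arena,
    build_starmaze,
    build_vista_world,
    starmaze_pose,
)
from .hippocampus import (
    NoRouteError,
    active_place_cell,
    agd_population,
    plan_route,
)
from .motor import AgentState, step_kinematics, velocity_command
from .neural_coding import NoiseModel, bearing, wrap_angle
from .parietal import (
    CueVector,
    MovementCellActivity,
    RouteMemory,
    conjunctive_response,
    ecd_population,
    egcd_cue_following,
    egcd_modulate,
    movement_cells,
    record_turn_sequence,
    sense_cues,
    sequential_step,
)
from .retrosplenial import (
    ConfidenceState,
    HeadDirectionState,
    egocentric_peak,
    select_strategy,
    transform_to_egocentric,
    update_confidence,
)

STRATEGIES_STARMAZE = ("allocentric", "route_sequential")
STRATEGIES_VISTA = ("allocentric", "egocentric", "route_cue")


@dataclass
class TrialLog:
    """Per-step records, events and the trial outcome."""

    records: List[dict] = field(default_factory=list)
    events: List[Tuple[int, str, str]] = field(default_factory=list)
    outcome: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def steps(self) -> int:
        return len(self.records)


@dataclass
class ExperimentResult:
    """Aggregate of one experiment run."""

    labels: List[str]
    counts: Dict[str, int]
    percentages: Dict[str, float]
    trials: List[TrialLog]
    master_seed: int
    config_yaml: str
    extras: dict = field(default_factory=dict)


class Simulation:
    """One trial's world state and the per-step update."""

    def __init__(
        self,
        env: Environment,
        config: ModelConfig,
        strategies: Sequence[str],
        rng: np.random.Generator,
        goal_position,
        goal_landmark: Optional[str] = None,
        initial_strategy: Optional[str] = None,
        route_memory: Optional[RouteMemory] = None,
    ):
        self.env = env
        self.config = config
        self.strategies = list(strategies)
        self.rng = rng
        self.noise = NoiseModel(config.neural.noise_sd, mode=config.neural.noise_mode, rng=rng)
        self.agent = AgentState.from_config(env.start_position, env.start_heading, config.motor)
        self.goal_position = np.asarray(goal_position, dtype=float)
        self.goal_landmark = goal_landmark
        self.confidence = ConfidenceState.initial(self.strategies, config.confidence)
        self.strategy = initial_strategy or self.strategies[0]
        self.route_memory = route_memory
        self.cue_route_targets: List[Tuple[str, np.ndarray]] = []
        self.cue_route_index = 0
        self._route_cue_planned = False
        self.t = 0
        self.prev_goal_distance: Optional[float] = None
        self.place_cell: Optional[str] = None
        self._steps_at_place = 0
        self._progress_event = False
        self.log = TrialLog()

    # -- helpers -------------------------------------------------------
    def goal_distance(self) -> float:
        return float(np.linalg.norm(self.agent.position - self.goal_position))

    def _plan_cue_route(self) -> None:
        """(Re)plan the cue-following target list from the nearest landmark."""
        self.cue_route_targets = []
        self.cue_route_index = 0
        try:
            start = active_place_cell(self.agent.position, self.env.map)
            if self.goal_landmark is not None:
                path = plan_route(self.env.map, start, self.goal_landmark)
                self.cue_route_targets = [(lid, self.env.map.position(lid)) for lid in path]
        except (NoRouteError, ValueError):
            self.cue_route_targets = []
        self.cue_route_targets.append(("goal", self.goal_position.copy()))
        self._route_cue_planned = True

    def _confidence_events(self, egd_ego_peak: Optional[float]) -> set:
        cfg = self.config.arbitration
        events = {"step"}
        d = self.goal_distance()
        if self.prev_goal_distance is not None:
            if d < self.prev_goal_distance - cfg.distance_deadband:
                events.add("approaching")
            elif d > self.prev_goal_distance + cfg.distance_deadband:
                events.add("distance_increased")
        self.prev_goal_distance = d
        if egd_ego_peak is not None and abs(egd_ego_peak) <= cfg.alignment_tolerance:
            events.add("heading_aligned")
        if self._progress_event:
            events.add("progress")
            self._progress_event = False
        if self._steps_at_place > cfg.stuck_threshold:
            events.add("stuck")
        return events

    def _update_place_cell(self) -> None:
        if len(self.env.map.landmarks) == 0:
            return
        place = active_place_cell(self.agent.position, self.env.map)
        if place == self.place_cell:
            self._steps_at_place += 1
        else:
            self.place_cell = place
            self._steps_at_place = 0

    # -- strategy dispatch --------------------------------------------
    def _movement(self, egd, cue_vectors) -> Tuple[MovementCellActivity, Optional[float]]:
        """Movement-cell drive (and optional turn clip) for the active strategy."""
        ncfg = self.config.neural
        if self.strategy == "allocentric":
            return movement_cells(egd), None
        if self.strategy == "egocentric":
            ecd = ecd_population(cue_vectors, self.config.sensory, ncfg.sigma, ncfg.n_units, self.noise)
            if ecd.is_degenerate:
                return MovementCellActivity(0.0, 1.0, 0.0), None
            egcd = egcd_modulate(ecd, egd, ncfg.sigma_weight)
            return movement_cells(egcd), None
        if self.strategy == "route_cue":
            if not self._route_cue_planned:
                self._plan_cue_route()
            while self.cue_route_index < len(self.cue_route_targets):
                tid, tpos = self.cue_route_targets[self.cue_route_index]
                dist = float(np.linalg.norm(self.agent.position - tpos))
                if dist <= self.config.capture_radius:
                    self.cue_route_index += 1
                    self._progress_event = True
                    continue
                ego = wrap_angle(bearing(self.agent.position, tpos) - self.agent.heading)
                bump = egcd_cue_following(CueVector(tid, dist, ego), ncfg.sigma, ncfg.n_units, self.noise)
                return movement_cells(bump), None
            # route exhausted: home on the goal cue directly
            return movement_cells(egd), None
        if self.strategy == "route_sequential":
            override = sequential_step(
                self.route_memory,
                self.agent.position,
                self.agent.heading,
                self.env.map,
                self.config.capture_radius,
                self.config.turn_tolerance,
            )
            if override is None:
                return MovementCellActivity(0.0, 1.0, 0.0), None
            if override.turn_remaining is None:
                return override.mv, None
            return override.mv, override.turn_remaining
        raise ValueError(f"unknown strategy: {self.strategy}")

    # -- the per-step loop --------------------------------------------
    def step(self, arbitrate: bool = True) -> None:
        """One full pass: sense -> HPC -> RSC -> PPC -> motor."""
        ncfg = self.config.neural
        cue_vectors = sense_cues(
            self.agent.position, self.agent.heading, self.env.active_cues, self.config.sensory
        )
        self._update_place_cell()

        # hippocampus: allocentric goal direction from the live position
        goal_dir = bearing(self.agent.position, self.goal_position)
        agd = agd_population(goal_dir % 360.0, ncfg.sigma, ncfg.n_units, self.noise)
        hd = HeadDirectionState.from_heading(self.agent.heading, ncfg.sigma, ncfg.n_units, self.noise)
        egd = transform_to_egocentric(agd, hd, self.noise)
        ego_peak = egocentric_peak(egd)

        # retrosplenial: confidence dynamics and periodic arbitration
        seq_progress_before = self.route_memory.progress_index if self.route_memory else None
        events = self._confidence_events(ego_peak)
        self.confidence = update_confidence(self.confidence, events, self.strategy)
        acfg = self.config.arbitration
        if arbitrate and self.t >= acfg.initial_hold and self.t % acfg.period == 0:
            decision = select_strategy(self.confidence, self.rng, self.config.arbitration.temperature)
            if decision.chosen != self.strategy:
                self.log.events.append((self.t, "strategy_switch", f"{self.strategy}->{decision.chosen}"))
                if decision.chosen == "route_cue":
                    self._route_cue_planned = False  # replan from here
            self.strategy = decision.chosen

        # parietal + motor
        mv, turn_limit = self._movement(egd, cue_vectors)
        if self.route_memory is not None and seq_progress_before is not None:
            if self.route_memory.progress_index > seq_progress_before:
                self._progress_event = True
        v = velocity_command(mv)
        self.agent = step_kinematics(self.agent, v, self.env.walls, turn_limit)

        self.log.records.append(
            {
                "t": self.t,
                "x": float(self.agent.position[0]),
                "y": float(self.agent.position[1]),
                "heading": float(self.agent.heading),
                "strategy": self.strategy,
                "v_left": v.v_left,
                "v_right": v.v_right,
                **{f"conf_{s}": self.confidence.values[s] for s in self.strategies},
            }
        )
        self.t += 1


def simulation_step(sim: Simulation) -> Simulation:
    """Advance a simulation by one step (thin functional wrapper)."""
    sim.step()
    return sim


# ---------------------------------------------------------------------------
# blinking-light experiment


def probe_conjunctive_surface(
    cells: Sequence[Tuple[float, float]],
    config: ModelConfig,
    noise: NoiseModel,
    grid_step: float = 2.0,
) -> Dict[Tuple[float, float], dict]:
    """Tuning surface of conjunctive cells on a full (HD, ECD) grid.

    For every grid heading the HD population is built (with the run's
    noise model) and read out at the cell's preferred head direction;
    likewise the ECD population for a single cue placed at every grid
    egocentric angle (at the activation-neutral distance D).  The
    surface is the outer product of the two tuning reads — the
    separability that defines a conjunctive cell.
    """
    ncfg = config.neural
    hd_grid = np.arange(0.0, 360.0, grid_step)
    ecd_grid = np.arange(-180.0 + grid_step, 180.0 + grid_step / 2, grid_step)
    out = {}
    for pref_hd, pref_ecd in cells:
        f = np.empty(hd_grid.size)
        for i, h in enumerate(hd_grid):
            hd = HeadDirectionState.from_heading(h, ncfg.sigma, ncfg.n_units, noise)
            f[i] = hd.population.value_at(pref_hd)
        g = np.empty(ecd_grid.size)
        for j, e in enumerate(ecd_grid):
            pop = ecd_population(
                [CueVector("probe", config.sensory.D, e)], config.sensory, ncfg.sigma, ncfg.n_units, noise
            )
            g[j] = pop.value_at(pref_ecd)
        surface = np.outer(f, g)
        k = int(np.argmax(surface))
        i, j = divmod(k, ecd_grid.size)
        out[(pref_hd, pref_ecd)] = {
            "hd_grid": hd_grid,
            "ecd_grid": ecd_grid,
            "surface": surface,
            "argmax": (float(hd_grid[i]), float(ecd_grid[j])),
        }
    return out


def run_blinking_light(
    config: Optional[ModelConfig] = None,
    seed: int = 0,
    n_steps: Optional[int] = None,
    record_cells: Sequence[Tuple[float, float]] = ((310.0, 150.0), (350.0, -90.0)),
    radius: float = 5.0,
    n_lights: int = 32,
) -> Tuple[TrialLog, dict]:
    """Egocentric cue chasing in the circular arena.

    The hippocampal and retrosplenial modules are disabled: steering is
    driven directly by the ECD population of the single active light.
    Returns the trial log and a dict with per-step conjunctive-cell
    recordings plus their probed tuning surfaces.
    """
    config = config or blinking_config()
    n_steps = n_steps or config.step_budget
    rng = np.random.default_rng(seed)
    env = build_blinking_light_arena(radius=radius, n_lights=n_lights, rng=rng)
    noise = NoiseModel(config.neural.noise_sd, mode=config.neural.noise_mode, rng=rng)
    agent = AgentState.from_config(env.start_position, env.start_heading, config.motor)
    ncfg = config.neural

    log = TrialLog()
    cell_rows: List[dict] = []
    cue_switches = 0
    visited = set()
    for t in range(n_steps):
        active = env.active_cues[0]
        cue_vectors = sense_cues(agent.position, agent.heading, [active], config.sensory)
        hd = HeadDirectionState.from_heading(agent.heading, ncfg.sigma, ncfg.n_units, noise)
        ecd = ecd_population(cue_vectors, config.sensory, ncfg.sigma, ncfg.n_units, noise)
        mv = movement_cells(ecd) if not ecd.is_degenerate else MovementCellActivity(0, 1, 0)
        v = velocity_command(mv)
        agent = step_kinematics(agent, v, env.walls)

        row = {
            "t": t,
            "x": float(agent.position[0]),
            "y": float(agent.position[1]),
            "heading": float(agent.heading),
            "cue": active.id,
            "cue_ego": cue_vectors[0].egocentric_direction if cue_vectors else np.nan,
        }
        for pref_hd, pref_ecd in record_cells:
            row[f"conj_{int(pref_hd)}_{int(pref_ecd)}"] = conjunctive_response(pref_hd, pref_ecd, hd, ecd)
        cell_rows.append(row)
        log.records.append(
            {"t": t, "x": row["x"], "y": row["y"], "heading": row["heading"],
             "strategy": "egocentric", "v_left": v.v_left, "v_right": v.v_right}
        )
        visited.add(active.id)
        if advance_blinking_cue(env, agent.position, config.capture_radius, rng):
            cue_switches += 1
            log.events.append((t, "cue_switch", f"{active.id}->{env.active_cues[0].id}"))
    log.outcome = {"cue_switches": cue_switches, "distinct_cues_visited": len(visited), "steps": n_steps}

    surfaces = probe_conjunctive_surface(record_cells, config, noise)
    recordings = {"cells": pd.DataFrame(cell_rows), "surfaces": surfaces}
    return log, recordings


# ---------------------------------------------------------------------------
# starmaze experiment


def train_starmaze_sequence(env: Environment) -> RouteMemory:
    """Supervised training traversal alley 1 -> alley 7.

    The shortest landmark route is walked and the signed heading change
    at every junction recorded as the stored motor sequence.
    """
    route = plan_route(env.map, env.metadata["train_start"], env.metadata["train_goal"])
    seq = record_turn_sequence(env.map, route)
    return RouteMemory(kind="sequential_egocentric", sequence=seq)


def classify_starmaze_trial(log: TrialLog, env: Environment) -> str:
    """Label a probe trial from its trajectory alone.

    * ``egocentric`` — terminated at the alley-1 end (pure replay);
    * ``allocentric`` — terminated at the goal (alley-7 end) without
      ever crossing the ring toward alley 1;
    * ``mixed`` — crossed the ring toward alley 1 (passed the sentinel
      junction or entered the alley-1 arm) and then terminated at the
      goal;
    * ``timeout`` — the step budget ran out with no terminal.
    """
    terminal = log.outcome.get("terminal")
    if terminal is None:
        return "timeout"
    if terminal == env.metadata["egocentric_terminal"]:
        return "egocentric"
    sentinel = np.asarray(env.metadata["mixed_sentinel_xy"], dtype=float)
    a1 = env.map.position(env.metadata["egocentric_terminal"])
    capture = log.outcome.get("capture_radius", 0.5)
    alley1 = env.regions.get("alley_1")
    from shapely.geometry import Point

    for rec in log.records:
        pos = np.array([rec["x"], rec["y"]])
        if float(np.linalg.norm(pos - sentinel)) <= capture or float(np.linalg.norm(pos - a1)) <= capture:
            return "mixed"
        if alley1 is not None and alley1.covers(Point(rec["x"], rec["y"])):
            return "mixed"
    return "allocentric"


def run_starmaze_trial(
    env: Environment,
    trained: RouteMemory,
    config: ModelConfig,
    rng: np.random.Generator,
) -> TrialLog:
    """One probe trial from the alley-5 end."""
    start_pos, start_heading = starmaze_pose(env, env.metadata["probe_start"])
    route = RouteMemory(kind="sequential_egocentric", sequence=list(trained.sequence))
    initial = "allocentric" if rng.random() < 0.25 else "route_sequential"
    sim = Simulation(
        replace_start(env, start_pos, start_heading),
        config,
        STRATEGIES_STARMAZE,
        rng,
        goal_position=env.map.position(env.metadata["train_goal"]),
        goal_landmark=env.metadata["train_goal"],
        initial_strategy=initial,
        route_memory=route,
    )
    goal_pos = env.map.position(env.metadata["train_goal"])
    a1_pos = env.map.position(env.metadata["egocentric_terminal"])
    sim.log.outcome["initial_strategy"] = initial
    sim.log.outcome["capture_radius"] = config.capture_radius
    for _ in range(config.step_budget):
        sim.step()
        if float(np.linalg.norm(sim.agent.position - goal_pos)) <= config.capture_radius:
            sim.log.outcome["terminal"] = env.metadata["train_goal"]
            break
        if (
            sim.strategy == "route_sequential"
            and float(np.linalg.norm(sim.agent.position - a1_pos)) <= config.capture_radius
        ):
            sim.log.outcome["terminal"] = env.metadata["egocentric_terminal"]
            break
    sim.log.outcome["steps"] = sim.t
    return sim.log


def replace_start(env: Environment, position, heading: float) -> Environment:
    """Shallow-copied environment with a different start pose."""
    from dataclasses import replace as _dc_replace

    return _dc_replace(env, start_position=tuple(position), start_heading=float(heading))


def run_starmaze(
    config: Optional[ModelConfig] = None,
    n_trials: int = 130,
    seed: int = 0,
) -> ExperimentResult:
    """Probe-trial batch: train once, probe ``n_trials`` times.

    Each trial draws its initial strategy 25/75 (allocentric /
    sequential-egocentric) and then runs the confidence/softmax
    arbitration; trials are classified from their trajectories and
    aggregated into counts and percentages.
    """
    config = config or starmaze_config()
    env = build_starmaze()
    trained = train_starmaze_sequence(env)
    seqs = np.random.SeedSequence(seed).spawn(n_trials)
    labels: List[str] = []
    trials: List[TrialLog] = []
    for child in seqs:
        rng = np.random.default_rng(child)
        log = run_starmaze_trial(env, trained, config, rng)
        label = classify_starmaze_trial(log, env)
        log.outcome["label"] = label
        labels.append(label)
        trials.append(log)
    categories = ("allocentric", "egocentric", "mixed", "timeout")
    counts = {c: labels.count(c) for c in categories}
    percentages = {c: 100.0 * counts[c] / n_trials for c in categories}
    return ExperimentResult(
        labels=labels,
        counts=counts,
        percentages=percentages,
        trials=trials,
        master_seed=seed,
        config_yaml=config.to_yaml(),
        extras={"trained_sequence": list(trained.sequence)},
    )


def mean_confidence_traces(result: ExperimentResult, strategies=STRATEGIES_STARMAZE) -> Dict[str, pd.DataFrame]:
    """Per-category mean confidence traces over time (trace-figure analogue)."""
    out = {}
    for label in ("allocentric", "egocentric", "mixed"):
        logs = [t for t in result.trials if t.outcome.get("label") == label]
        if not logs:
            continue
        horizon = max(t.steps for t in logs)
        data = {}
        for s in strategies:
            traces = np.full((len(logs), horizon), np.nan)
            for i, t in enumerate(logs):
                vals = [rec[f"conf_{s}"] for rec in t.records]
                traces[i, : len(vals)] = vals
            data[s] = np.nanmean(traces, axis=0)
        out[label] = pd.DataFrame(data)
    return out


# ---------------------------------------------------------------------------
# vista-space experiment


def run_vista_trial(
    env: Environment,
    config: ModelConfig,
    rng: np.random.Generator,
    goal_region: Optional[str] = None,
    strategies: Sequence[str] = STRATEGIES_VISTA,
) -> TrialLog:
    """One vista trial: randomize cue positions, pick a goal, navigate."""
    layout = env.metadata["layout"]
    region_size = env.metadata["region_size"]
    start_region = env.metadata["start_region"]
    spacing = region_size + env.metadata["gap"]
    # scatter one cue per region (margin 1 from the walls)
    for cue in env.cues:
        rid = cue.id.replace("cue", "")
        col, row = layout[rid]
        cue.position = (
            col * spacing + 1.0 + rng.random() * (region_size - 2.0),
            row * spacing + 1.0 + rng.random() * (region_size - 2.0),
        )
    candidates = sorted(r for r in layout if r != start_region)
    goal_region = goal_region or candidates[int(rng.integers(len(candidates)))]
    goal_cue = env.cue(f"cue{goal_region}")
    env.goal_id = goal_cue.id

    sim = Simulation(
        env,
        config,
        strategies,
        rng,
        goal_position=goal_cue.position,
        goal_landmark=f"c{goal_region}",
    )
    decision = select_strategy(sim.confidence, rng, config.arbitration.temperature)
    sim.strategy = decision.chosen
    sim.log.outcome["goal_region"] = goal_region
    sim.log.outcome["capture_radius"] = config.capture_radius
    goal_pos = np.asarray(goal_cue.position)
    for _ in range(config.step_budget):
        sim.step()
        if float(np.linalg.norm(sim.agent.position - goal_pos)) <= config.capture_radius:
            sim.log.outcome["terminal"] = goal_cue.id
            break
    sim.log.outcome["reached"] = "terminal" in sim.log.outcome
    sim.log.outcome["steps"] = sim.t
    sim.log.outcome["goal_position"] = (float(goal_pos[0]), float(goal_pos[1]))
    return sim.log


def strategy_contribution(log: TrialLog, env: Environment, strategies=STRATEGIES_VISTA) -> Dict[str, float]:
    """Percentage of goal-ward progress credited to each strategy.

    For every step the shortest-route length from the agent (via its
    nearest landmark) to the goal landmark is computed; a step counts as
    progress when that length strictly decreased, and the credit goes to
    the strategy active at that step.
    """
    goal_region = log.outcome.get("goal_region")
    goal_lm = f"c{goal_region}"
    spl = nx.single_source_dijkstra_path_length(env.map.graph, goal_lm, weight="distance")
    positions = np.array([[rec["x"], rec["y"]] for rec in log.records])
    lm_ids = [lm.id for lm in env.map.landmarks]
    lm_pos = np.array([env.map.position(l) for l in lm_ids])
    d_all = np.linalg.norm(positions[:, None, :] - lm_pos[None, :, :], axis=2)
    nearest = np.argmin(d_all, axis=1)
    route_len = np.array(
        [d_all[i, nearest[i]] + spl.get(lm_ids[nearest[i]], np.inf) for i in range(len(positions))]
    )
    progressing = route_len[1:] < route_len[:-1] - 1e-9
    counts = {s: 0 for s in strategies}
    for i, prog in enumerate(progressing, start=1):
        if prog:
            counts[log.records[i]["strategy"]] += 1
    total = sum(counts.values())
    if total == 0:
        import warnings

        warnings.warn("no progressing steps in trial; contributions undefined (all zero)")
        return {s: 0.0 for s in strategies}
    return {s: 100.0 * c / total for s, c in counts.items()}


def run_vista(
    config: Optional[ModelConfig] = None,
    n_trials: int = 80,
    seed: int = 0,
    blocked: Optional[List[Tuple[str, str]]] = None,
    strategies: Sequence[str] = STRATEGIES_VISTA,
) -> ExperimentResult:
    """Vista-space batch: random goals, full arbitration, contributions."""
    config = config or vista_config()
    seqs = np.random.SeedSequence(seed).spawn(n_trials)
    trials: List[TrialLog] = []
    labels: List[str] = []
    contributions: List[Dict[str, float]] = []
    for child in seqs:
        rng = np.random.default_rng(child)
        env = build_vista_world(blocked=blocked)
        log = run_vista_trial(env, config, rng, strategies=strategies)
        contrib = strategy_contribution(log, env, strategies)
        log.outcome["contribution"] = contrib
        contributions.append(contrib)
        labels.append("reached" if log.outcome["reached"] else "timeout")
        trials.append(log)
    counts = {c: labels.count(c) for c in ("reached", "timeout")}
    percentages = {c: 100.0 * counts[c] / n_trials for c in counts}
    mean_contrib = {
        s: float(np.mean([c[s] for c in contributions])) for s in strategies
    }
    return ExperimentResult(
        labels=labels,
        counts=counts,
        percentages=percentages,
        trials=trials,
        master_seed=seed,
        config_yaml=config.to_yaml(),
        extras={"mean_contribution": mean_contrib, "contributions": contributions},
    )


__all__ = [
    "STRATEGIES_STARMAZE",
    "STRATEGIES_VISTA",
    "TrialLog",
    "ExperimentResult",
    "Simulation",
    "simulation_step",
    "run_blinking_light",
    "probe_conjunctive_surface",
    "train_starmaze_sequence",
    "run_starmaze_trial",
    "run_starmaze",
    "classify_starmaze_trial",
    "mean_confidence_traces",
    "run_vista_trial",
    "run_vista",
    "strategy_contribution",
]
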