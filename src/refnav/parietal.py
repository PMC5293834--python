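"""Sensory cue coding, goal-modulated steering and route execution.

The parietal module turns perception into movement-cell drive.  Cues are
sensed as (distance, egocentric direction) pairs; egocentric cue
direction (ECD) cells respond with distance-attenuated Gaussian bumps
(gain D/d).  For the egocentric strategy the goal signal (EGD) modulates
the ECD population through broad weight vectors so that the cue nearest
the goal direction wins (EGCD cells).  The cue-following route strategy
drives EGCD directly with a bump at the next route cue; the sequential-
egocentric route strategy bypasses the populations entirely and replays
stored turn commands at choice points.  Movement cells (left, forward,
right) integrate EGCD activity over fixed hemifield bands, and
conjunctive cells multiply head-direction and cue-direction tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import SensoryConfig
from .neural_coding import (
    CellPopulation,
    NoiseModel,
    add_noise_and_normalize,
    bearing,
    encode_population,
    gaussian_tuning,
    wrap_angle,
)
from .retrosplenial import HeadDirectionState


@dataclass(frozen=True)
class CueVector:
    """A perceived cue: distance and egocentric direction from the agent."""

    cue_id: str
    distance: float
    egocentric_direction: float  # degrees in (-180, 180]

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("cue distance must be positive (agent cannot sit on a cue)")


def sense_cues(position, heading: float, cues, params: SensoryConfig) -> List[CueVector]:
    """Measure distance and egocentric direction of every visible cue.

    ``cues`` is an iterable of objects with ``id`` and ``position``
    attributes (only active/visible cues should be passed in).  Cues
    outside the field of view or beyond the optional visibility radius
    are dropped.
    """
    pos = np.asarray(position, dtype=float)
    out: List[CueVector] = []
    for cue in cues:
        cue_pos = np.asarray(cue.position, dtype=float)
        d = float(np.linalg.norm(cue_pos - pos))
        if d == 0.0:
            raise ValueError(f"cue {cue.id} coincides with the agent position")
        ego = wrap_angle(bearing(pos, cue_pos) - heading)
        if abs(ego) > params.field_of_view / 2.0:
            continue
        if params.visibility_radius is not None and d > params.visibility_radius:
            continue
        out.append(CueVector(cue.id, d, ego))
    return out


def ecd_raw(cue_vectors: Sequence[CueVector], params: SensoryConfig, sigma: float = 10.0, n_units: int = 360) -> np.ndarray:
    """Raw (pre-noise, pre-normalization) ECD activities.

    Each unit sums a distance-attenuated Gaussian bump (gain D/d) over
    all cues.
    """
    preferred = np.arange(n_units, dtype=float) * (360.0 / n_units)
    acts = np.zeros(n_units)
    for cv in cue_vectors:
        acts += (params.D / cv.distance) * gaussian_tuning(preferred, cv.egocentric_direction % 360.0, sigma)
    return acts


def ecd_population(
    cue_vectors: Sequence[CueVector],
    params: SensoryConfig,
    sigma: float = 10.0,
    n_units: int = 360,
    noise: Optional[NoiseModel] = None,
) -> CellPopulation:
    """ECD population: distance-attenuated cue bumps, noise, normalization.

    With no visible cue the population is all-zero and flagged
    degenerate (``is_degenerate``); no normalization is applied.
    """
    preferred = np.arange(n_units, dtype=float) * (360.0 / n_units)
    if not cue_vectors:
        return CellPopulation(preferred, np.zeros(n_units), sigma)
    pop = CellPopulation(preferred, ecd_raw(cue_vectors, params, sigma, n_units), sigma)
    return add_noise_and_normalize(pop, noise)


def goal_weight_matrix(n_units: int = 360, sigma_weight: float = 80.0) -> np.ndarray:
    """W[i, m] = Gaussian weight between EGCD unit i and EGD unit m (broad, sigma 80)."""
    preferred = np.arange(n_units, dtype=float) * (360.0 / n_units)
    delta = wrap_angle(preferred[:, None] - preferred[None, :])
    return np.exp(-(delta**2) / sigma_weight**2)


_WEIGHT_CACHE: dict = {}


def _weights(n_units: int, sigma_weight: float) -> np.ndarray:
    key = (n_units, sigma_weight)
    if key not in _WEIGHT_CACHE:
        _WEIGHT_CACHE[key] = goal_weight_matrix(n_units, sigma_weight)
    return _WEIGHT_CACHE[key]


def egcd_modulate(
    ecd: CellPopulation,
    egd: CellPopulation,
    sigma_weight: float = 80.0,
) -> CellPopulation:
    """Goal-modulated cue signal (EGCD).

    egcd_i = ecd_i * sum_m [ egd_m * w_i(m)        if egd_m > 0.5
                             egd_m * (w_i(m) - 1)  otherwise ],

    with w the broad Gaussian weight matrix.  Strong EGD units excite
    cue bumps near the goal direction; weak ones inhibit.  Negative
    results are clamped to zero and the population max-normalized if
    anything survives.
    """
    n = len(ecd)
    if len(egd) != n:
        raise ValueError("ECD and EGD populations must have equal size")
    W = _weights(n, sigma_weight)
    egd_acts = egd.activities
    strong = egd_acts > 0.5
    # sum_m egd_m*W[i,m]*strong + egd_m*(W[i,m]-1)*(1-strong)
    factor = W @ egd_acts - float(np.sum(egd_acts[~strong]))
    acts = np.clip(ecd.activities * factor, 0.0, None)
    peak = float(acts.max()) if acts.size else 0.0
    if peak > 0.0:
        acts = acts / peak
    return CellPopulation(ecd.preferred_angles.copy(), acts, ecd.sigma)


def egcd_cue_following(
    goal_cue: CueVector,
    sigma: float = 10.0,
    n_units: int = 360,
    noise: Optional[NoiseModel] = None,
) -> CellPopulation:
    """Route (cue-following) EGCD: a pure bump at the goal cue's direction.

    Distance is ignored — route goal cues are taken to be visible from
    everywhere.
    """
    pop = encode_population(goal_cue.egocentric_direction % 360.0, sigma, n_units)
    return add_noise_and_normalize(pop, noise)


# ---------------------------------------------------------------------------
# movement cells


@dataclass
class MovementCellActivity:
    mv_left: float
    mv_forward: float
    mv_right: float

    def __post_init__(self):
        if min(self.mv_left, self.mv_forward, self.mv_right) < 0:
            raise ValueError("movement-cell activations must be non-negative")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.mv_left, self.mv_forward, self.mv_right)


_BAND_CACHE: dict = {}


def _bands(n_units: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hemifield summation bands over egocentric angle wrap(preferred).

    Left: [-179, 0]; forward: [-54, 54]; right: [1, 180] — the bands
    overlap at the front exactly as printed (180/109/180 units for
    n=360).
    """
    if n_units not in _BAND_CACHE:
        ego = wrap_angle(np.arange(n_units, dtype=float) * (360.0 / n_units))
        left = (ego >= -179.0) & (ego <= 0.0)
        forward = (ego >= -54.0) & (ego <= 54.0)
        right = (ego >= 1.0) & (ego <= 180.0)
        _BAND_CACHE[n_units] = (left, forward, right)
    return _BAND_CACHE[n_units]


def movement_cells(pop: CellPopulation) -> MovementCellActivity:
    """Integrate an egocentric population into (left, forward, right) drive."""
    if len(pop) != 360:
        raise ValueError("movement cells expect a 360-unit egocentric population")
    left, forward, right = _bands(len(pop))
    acts = pop.activities
    return MovementCellActivity(
        mv_left=float(acts[left].sum()),
        mv_forward=float(acts[forward].sum()),
        mv_right=float(acts[right].sum()),
    )


# ---------------------------------------------------------------------------
# route memory and sequential-egocentric execution


@dataclass
class RouteMemory:
    """A stored route: turn commands at choice points, or a cue sequence."""

    kind: str  # "sequential_egocentric" | "cue_following"
    sequence: List[Tuple[str, float]] = field(default_factory=list)
    progress_index: int = 0
    # transient replay state (sequential kind)
    turn_target: Optional[float] = None
    last_trigger: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("sequential_egocentric", "cue_following"):
            raise ValueError(f"unknown route kind: {self.kind}")
        if self.progress_index > len(self.sequence):
            raise ValueError("progress_index beyond sequence length")

    @property
    def exhausted(self) -> bool:
        return self.progress_index >= len(self.sequence) and self.turn_target is None

    def reset(self) -> None:
        self.progress_index = 0
        self.turn_target = None
        self.last_trigger = None


@dataclass
class MovementOverride:
    """Direct steering command bypassing the population pathway.

    ``turn_remaining`` is the signed angle still to rotate; None means
    drive straight ahead.
    """

    turn_remaining: Optional[float] = None

    @property
    def mv(self) -> MovementCellActivity:
        if self.turn_remaining is None:
            return MovementCellActivity(0.0, 1.0, 0.0)
        if self.turn_remaining < 0:  # toward the left hemifield
            return MovementCellActivity(1.0, 0.0, 0.0)
        return MovementCellActivity(0.0, 0.0, 1.0)


def sequential_step(
    route: RouteMemory,
    position,
    heading: float,
    cmap,
    capture_radius: float,
    turn_tolerance: float = 2.0,
) -> Optional[MovementOverride]:
    """One control decision of the sequential-egocentric strategy.

    The agent drives straight until it encounters a choice-point
    landmark, then executes the next stored turn (a saturated steering
    drive, trimmed on the final step), advances its progress and
    continues straight.  Replay is id-blind: any choice-point landmark
    triggers the next stored command, so a sequence trained from one
    start replays from another.  Returns None once the sequence is
    exhausted.
    """
    if route.kind != "sequential_egocentric":
        raise ValueError("sequential_step requires a sequential_egocentric route")
    pos = np.asarray(position, dtype=float)

    if route.turn_target is not None:
        remaining = wrap_angle(route.turn_target - heading)
        if abs(remaining) <= turn_tolerance:
            route.turn_target = None
            route.progress_index += 1
            return MovementOverride(None)
        return MovementOverride(remaining)

    if route.progress_index >= len(route.sequence):
        return None

    # release the trigger guard once we have left the last junction
    if route.last_trigger is not None:
        d_last = float(np.linalg.norm(pos - cmap.position(route.last_trigger)))
        if d_last > capture_radius:
            route.last_trigger = None

    near = [
        lm
        for lm in cmap.landmarks
        if lm.is_choice_point
        and lm.id != route.last_trigger
        and float(np.linalg.norm(pos - np.asarray(lm.position))) <= capture_radius
    ]
    if near:
        trigger = min(
            near, key=lambda lm: (float(np.linalg.norm(pos - np.asarray(lm.position))), lm.id)
        )
        _, turn = route.sequence[route.progress_index]
        route.turn_target = wrap_angle(heading + turn)
        route.last_trigger = trigger.id
        return MovementOverride(wrap_angle(route.turn_target - heading))
    return MovementOverride(None)


def record_turn_sequence(cmap, route: Sequence[str], turn_threshold: float = 10.0) -> List[Tuple[str, float]]:
    """Derive the stored motor sequence of a supervised traversal.

    Walking the landmark route, the signed heading change at every
    interior landmark is computed from the incoming and outgoing edge
    bearings; changes above ``turn_threshold`` become stored
    (landmark, turn) commands.
    """
    commands: List[Tuple[str, float]] = []
    for prev, here, nxt in zip(route[:-2], route[1:-1], route[2:]):
        incoming = bearing(cmap.position(prev), cmap.position(here))
        outgoing = bearing(cmap.position(here), cmap.position(nxt))
        turn = wrap_angle(outgoing - incoming)
        if abs(turn) > turn_threshold:
            commands.append((here, float(turn)))
    return commands


# ---------------------------------------------------------------------------
# conjunctive cells


def conjunctive_response(
    pref_hd: float,
    pref_ecd: float,
    hd: HeadDirectionState,
    ecd: CellPopulation,
) -> float:
    """Product of HD activity at pref_hd and ECD activity at pref_ecd.

    Maximal when the agent faces pref_hd while a cue sits at pref_ecd;
    zero whenever no cue is visible.
    """
    if ecd.is_degenerate:
        return 0.0
    return hd.population.value_at(pref_hd) * ecd.value_at(pref_ecd)


__all__ = [
    "CueVector",
    "MovementCellActivity",
    "MovementOverride",
    "RouteMemory",
    "sense_cues",
    "ecd_raw",
    "ecd_population",
    "goal_weight_matrix",
    "egcd_modulate",
    "egcd_cue_following",
    "movement_cells",
    "sequential_step",
    "record_turn_sequence",
    "conjunctive_response",
]
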