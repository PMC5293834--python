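"""Head direction, the allocentric->egocentric transform and arbitration.

The retrosplenial module keeps a 360-unit head-direction population
driven by the agent's internal compass, shifts the allocentric goal
direction by the current heading to obtain the egocentric goal direction
(EGD; negative angles label the left visual hemifield), and maintains a
confidence value in [0, 1] for every navigation strategy.  Confidences
decay exponentially every step and receive event-driven bonuses or extra
decay (approach/recede to the goal, route progress, heading alignment,
stuck detection).  Every P steps a softmax over the confidences draws
the strategy to deploy next.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np

from .config import ConfidenceParams
from .neural_coding import (
    CellPopulation,
    DegeneratePopulationError,
    NoiseModel,
    add_noise_and_normalize,
    encode_population,
    population_peak,
    wrap_angle,
)

VALID_EVENTS = frozenset(
    {"step", "approaching", "distance_increased", "progress", "heading_aligned", "stuck"}
)


@dataclass
class HeadDirectionState:
    """Internal-compass heading and the HD population that encodes it."""

    heading: float
    population: CellPopulation

    @classmethod
    def from_heading(
        cls,
        heading: float,
        sigma: float = 10.0,
        n_units: int = 360,
        noise: Optional[NoiseModel] = None,
    ) -> "HeadDirectionState":
        pop = add_noise_and_normalize(encode_population(heading % 360.0, sigma, n_units), noise)
        return cls(heading=wrap_angle(heading), population=pop)


def transform_to_egocentric(
    agd: CellPopulation,
    hd: HeadDirectionState,
    noise: Optional[NoiseModel] = None,
) -> CellPopulation:
    """Shift the AGD signal by the decoded head direction into EGD.

    The EGD population encodes wrap(AGD_peak - heading): 0 means the
    goal lies dead ahead, -80 means 80 degrees into the left hemifield.
    """
    if agd.is_degenerate:
        raise DegeneratePopulationError("degenerate AGD input")
    egd_angle = wrap_angle(population_peak(agd) - population_peak(hd.population))
    pop = encode_population(egd_angle % 360.0, agd.sigma, len(agd))
    return add_noise_and_normalize(pop, noise)


def egocentric_peak(pop: CellPopulation) -> float:
    """Decoded peak of an egocentric population as an angle in (-180, 180]."""
    return wrap_angle(population_peak(pop))


@dataclass
class ConfidenceState:
    """Per-strategy confidence values plus their update rates."""

    values: Dict[str, float]
    params: ConfidenceParams = field(default_factory=ConfidenceParams)

    @classmethod
    def initial(cls, strategies: Iterable[str], params: Optional[ConfidenceParams] = None) -> "ConfidenceState":
        params = params or ConfidenceParams()
        return cls({s: params.initial for s in strategies}, params)

    def copy(self) -> "ConfidenceState":
        return ConfidenceState(dict(self.values), self.params)


def update_confidence(
    state: ConfidenceState,
    events: Iterable[str],
    active_strategy: str,
) -> ConfidenceState:
    """Apply one step of confidence dynamics.

    Order of operations: the global per-step decay first, then the
    event-driven multiplicative decays and additive bonuses, then a
    clamp to [0, 1].  Bonuses target the active strategy only, except
    the stuck rule, which penalizes the active strategy and boosts all
    others.
    """
    events = set(events)
    unknown = events - VALID_EVENTS
    if unknown:
        raise ValueError(f"unknown confidence events: {sorted(unknown)}")
    if active_strategy not in state.values:
        raise KeyError(f"unknown strategy: {active_strategy}")
    p = state.params
    values = dict(state.values)

    if "step" in events:
        values = {s: v * (1.0 - p.lambda_default) for s, v in values.items()}
    if "approaching" in events:
        values[active_strategy] += p.u_default
    if "distance_increased" in events:
        values[active_strategy] *= 1.0 - p.lambda_dist
    if "progress" in events and p.progress_bonus_enabled:
        values[active_strategy] += p.u_progress
    if "heading_aligned" in events:
        values[active_strategy] += p.u_heading_aligned
    if "stuck" in events and p.stuck_enabled:
        values[active_strategy] *= 1.0 - p.lambda_stuck
        for s in values:
            if s != active_strategy:
                values[s] += p.u_stuck

    values = {s: min(1.0, max(0.0, v)) for s, v in values.items()}
    return ConfidenceState(values, p)


@dataclass
class StrategyDecision:
    chosen: str
    probabilities: Dict[str, float]


def select_strategy(
    state: ConfidenceState,
    rng: np.random.Generator,
    temperature: float = 1.0,
) -> StrategyDecision:
    """Softmax draw over the confidence values.

    p_i = exp(c_i / T) / sum_j exp(c_j / T); one strategy is drawn from
    the categorical distribution via a single uniform draw over the
    cumulative partition of [0, 1) in strategy order.  Deterministic
    given (state, rng state, T).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    names: List[str] = list(state.values.keys())
    if not names:
        raise ValueError("no enabled strategies")
    c = np.array([state.values[s] for s in names], dtype=float) / temperature
    c -= c.max()  # numerical stability; softmax is shift-invariant
    expc = np.exp(c)
    probs = expc / expc.sum()
    r = float(rng.random())
    cumulative = np.cumsum(probs)
    idx = int(np.searchsorted(cumulative, r, side="right"))
    idx = min(idx, len(names) - 1)
    return StrategyDecision(names[idx], {s: float(p) for s, p in zip(names, probs)})


__all__ = [
    "VALID_EVENTS",
    "HeadDirectionState",
    "ConfidenceState",
    "StrategyDecision",
    "transform_to_egocentric",
    "egocentric_peak",
    "update_confidence",
    "select_strategy",
]
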