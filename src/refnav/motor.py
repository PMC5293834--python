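"""Differential-drive motor layer.

Movement-cell activity is combined into a two-wheel velocity vector,

    v = (mv_forward + mv_right, mv_forward + mv_left)   # (left, right)

normalized by twice its maximum so both wheels lie in [0, 0.5] and the
faster wheel is exactly 0.5.  The pose update is a standard
differential-drive step: mean wheel speed drives translation along the
heading, the wheel-speed difference drives rotation (a faster left wheel
rotates the agent toward positive — "right"-labelled — egocentric
angles, which is the orientation consistent with the hemifield bands and
wheel cross-wiring of the movement pathway).  Wheels can never run
backwards.  Collisions against wall segments are resolved by pushing the
body circle out of the wall, so motion along a wall degrades into a
slide rather than a dead stop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .config import MotorConfig
from .neural_coding import wrap_angle
from .parietal import MovementCellActivity


@dataclass
class AgentState:
    """Planar pose plus kinematic parameters."""

    position: np.ndarray
    heading: float  # allocentric degrees
    body_radius: float = 0.15
    speed_scale: float = 0.2
    wheelbase: float = 0.3

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.body_radius <= 0 or self.wheelbase <= 0:
            raise ValueError("body_radius and wheelbase must be positive")

    @classmethod
    def from_config(cls, position, heading: float, motor: MotorConfig) -> "AgentState":
        return cls(
            position=np.asarray(position, dtype=float),
            heading=float(heading),
            body_radius=motor.body_radius,
            speed_scale=motor.speed_scale,
            wheelbase=motor.wheelbase,
        )


@dataclass(frozen=True)
class VelocityCommand:
    v_left: float
    v_right: float

    def __post_init__(self):
        for v in (self.v_left, self.v_right):
            if not (0.0 <= v <= 0.5 + 1e-12):
                raise ValueError("wheel velocities must lie in [0, 0.5]")


def velocity_command(mv: MovementCellActivity) -> VelocityCommand:
    """Normalize movement-cell drive into wheel velocities.

    All-zero input halts the agent for this step.
    """
    raw_left = mv.mv_forward + mv.mv_right
    raw_right = mv.mv_forward + mv.mv_left
    peak = max(raw_left, raw_right)
    if peak <= 0.0:
        return VelocityCommand(0.0, 0.0)
    return VelocityCommand(raw_left / (2.0 * peak), raw_right / (2.0 * peak))


def _segment_closest_points(pos: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Closest point to ``pos`` on each segment of an (S, 2, 2) array."""
    a = segments[:, 0, :]
    b = segments[:, 1, :]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0.0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", pos[None, :] - a, ab) / denom, 0.0, 1.0)
    return a + t[:, None] * ab


def resolve_collisions(position: np.ndarray, body_radius: float, walls: Optional[np.ndarray], iterations: int = 4) -> np.ndarray:
    """Push the body circle out of every penetrated wall segment.

    Iterating a few times handles corners; the tangential motion
    component survives, which is what produces wall sliding.
    """
    if walls is None or len(walls) == 0:
        return position
    pos = position.astype(float, copy=True)
    for _ in range(iterations):
        closest = _segment_closest_points(pos, walls)
        delta = pos[None, :] - closest
        dist = np.linalg.norm(delta, axis=1)
        hit = dist < body_radius
        if not np.any(hit):
            break
        idx = int(np.argmin(np.where(hit, dist, np.inf)))
        d = dist[idx]
        if d < 1e-12:
            # dead-centre on a wall: push along the segment normal
            seg = walls[idx]
            tangent = seg[1] - seg[0]
            normal = np.array([-tangent[1], tangent[0]])
            normal /= max(np.linalg.norm(normal), 1e-12)
            pos = pos + normal * body_radius
        else:
            pos = closest[idx] + delta[idx] / d * (body_radius + 1e-9)
    return pos


def step_kinematics(
    agent: AgentState,
    v: VelocityCommand,
    walls: Optional[np.ndarray] = None,
    turn_limit: Optional[float] = None,
) -> AgentState:
    """Advance the pose one step and resolve wall collisions.

    ``turn_limit`` (degrees) optionally clips the rotation magnitude —
    used by the sequential-route replay to trim the final step of a
    stored turn to the exact commanded angle.
    """
    dtheta = math.degrees((v.v_left - v.v_right) * agent.speed_scale / agent.wheelbase)
    if turn_limit is not None:
        limit = abs(turn_limit)
        dtheta = max(-limit, min(limit, dtheta))
    heading = wrap_angle(agent.heading + dtheta)
    speed = 0.5 * (v.v_left + v.v_right) * agent.speed_scale
    direction = np.array([math.cos(math.radians(heading)), math.sin(math.radians(heading))])
    position = agent.position + speed * direction
    position = resolve_collisions(position, agent.body_radius, walls)
    return replace(agent, position=position, heading=heading)


__all__ = [
    "AgentState",
    "VelocityCommand",
    "velocity_command",
    "step_kinematics",
    "resolve_collisions",
]
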