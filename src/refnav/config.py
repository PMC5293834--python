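"""Global model configuration.

Every tunable of the navigation model lives here: population-code
parameters (tuning width, population size, noise), confidence dynamics
(decay and bonus rates), strategy-arbitration settings (softmax
temperature, re-evaluation period), sensory constants, agent kinematics
and per-experiment step budgets.  The three experiment runners construct
their configuration via :func:`blinking_config`, :func:`starmaze_config`
and :func:`vista_config`, which apply the per-experiment overrides
(the three parameter columns: common, starmaze-only, vista-only).

Configurations serialize to/from plain YAML so a run can snapshot the
exact settings it used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import yaml


@dataclass
class NeuralConfig:
    """Population-code parameters shared by all cell populations."""

    sigma: float = 10.0            # tuning width (degrees) for all populations
    sigma_weight: float = 80.0     # broad width for the goal-modulation weight vectors
    n_units: int = 360             # one unit per degree
    noise_sd: float = 0.05         # sd of the zero-mean Gaussian added to activities
    noise_mode: str = "gaussian"   # "gaussian" (zero-mean) | "literal" | "off"


@dataclass
class ConfidenceParams:
    """Confidence-dynamics rates (decay constants and event bonuses)."""

    initial: float = 0.8
    lambda_default: float = 0.02   # per-step decay of every strategy
    lambda_dist: float = 0.002     # extra decay of the active strategy when receding
    lambda_stuck: float = 0.02     # decay of the active strategy while stuck
    u_default: float = 0.025       # bonus to the active strategy when approaching
    u_ego: float = 0.05            # heading/goal alignment bonus (starmaze)
    u_progress: float = 0.25       # route-progress bonus (vista)
    u_direction: float = 0.005     # heading/goal alignment bonus (vista)
    u_stuck: float = 0.01          # bonus to the *other* strategies while stuck
    # experiment wiring: which bonuses are live and at what value
    u_heading_aligned: float = 0.0  # set per experiment (u_ego or u_direction)
    progress_bonus_enabled: bool = False
    stuck_enabled: bool = False


@dataclass
class ArbitrationConfig:
    temperature: float = 0.075    # softmax temperature (calibrated once, then frozen)
    period: int = 10              # re-evaluate the strategy every `period` steps
    initial_hold: int = 50        # steps before the first softmax re-evaluation
    stuck_threshold: int = 50     # steps near one place cell before "stuck" fires
    alignment_tolerance: float = 10.0  # |EGD peak| below this counts as aligned (deg)
    distance_deadband: float = 1e-6


@dataclass
class SensoryConfig:
    D: float = 3.0                 # distance-to-activation constant of the cue law
    field_of_view: float = 360.0   # degrees; cues outside the FOV are not sensed
    visibility_radius: Optional[float] = None  # optional hard cut-off (off by default)


@dataclass
class MotorConfig:
    speed_scale: float = 0.2       # length units per step per unit wheel velocity
    wheelbase: float = 0.3         # length units
    body_radius: float = 0.15      # collision radius of the agent


@dataclass
class ModelConfig:
    neural: NeuralConfig = field(default_factory=NeuralConfig)
    confidence: ConfidenceParams = field(default_factory=ConfidenceParams)
    arbitration: ArbitrationConfig = field(default_factory=ArbitrationConfig)
    sensory: SensoryConfig = field(default_factory=SensoryConfig)
    motor: MotorConfig = field(default_factory=MotorConfig)
    capture_radius: float = 0.5    # landmark/cue capture radius (length units)
    step_budget: int = 2000        # per-trial simulation step limit
    turn_tolerance: float = 2.0    # deg; a commanded turn is complete within this

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        raw = yaml.safe_load(text)
        return cls(
            neural=NeuralConfig(**raw["neural"]),
            confidence=ConfidenceParams(**raw["confidence"]),
            arbitration=ArbitrationConfig(**raw["arbitration"]),
            sensory=SensoryConfig(**raw["sensory"]),
            motor=MotorConfig(**raw["motor"]),
            capture_radius=raw["capture_radius"],
            step_budget=raw["step_budget"],
            turn_tolerance=raw["turn_tolerance"],
        )


def blinking_config(**overrides) -> ModelConfig:
    """Blinking-light experiment: arbitration off, egocentric steering only."""
    cfg = ModelConfig(step_budget=overrides.pop("step_budget", 5000))
    return _apply(cfg, overrides)


def starmaze_config(**overrides) -> ModelConfig:
    """Starmaze probe trials: allocentric vs sequential-egocentric arbitration.

    Only the rates of the starmaze column are live: the per-step decay,
    the approach bonus/receding decay and the heading-alignment bonus
    u_ego.  Route-progress and stuck handling stay disabled.
    """
    cfg = ModelConfig(step_budget=overrides.pop("step_budget", 20000))
    cfg.confidence.u_heading_aligned = cfg.confidence.u_ego
    cfg.confidence.progress_bonus_enabled = False
    cfg.confidence.stuck_enabled = False
    return _apply(cfg, overrides)


def vista_config(**overrides) -> ModelConfig:
    """Vista-space trials: full three-strategy arbitration with the vista rates."""
    cfg = ModelConfig(step_budget=overrides.pop("step_budget", 5000))
    cfg.confidence.u_heading_aligned = cfg.confidence.u_direction
    cfg.confidence.progress_bonus_enabled = True
    cfg.confidence.stuck_enabled = True
    # longer tenure and a sharper draw: a selected strategy needs enough
    # steps to traverse a region before being judged, and the large
    # route-progress bonus should then dominate the draw
    cfg.arbitration.period = 80
    cfg.arbitration.temperature = 0.02
    return _apply(cfg, overrides)


def _apply(cfg: ModelConfig, overrides: dict) -> ModelConfig:
    for key, value in overrides.items():
        obj = cfg
        parts = key.split(".")
        for part in parts[:-1]:
            obj = getattr(obj, part)
        if not hasattr(obj, parts[-1]):
            raise KeyError(f"unknown config key: {key}")
        setattr(obj, parts[-1], value)
    return cfg


__all__ = [
    "NeuralConfig",
    "ConfidenceParams",
    "ArbitrationConfig",
    "SensoryConfig",
    "MotorConfig",
    "ModelConfig",
    "blinking_config",
    "starmaze_config",
    "vista_config",
    "replace",
]
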