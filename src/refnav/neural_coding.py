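"""Gaussian-tuned population codes over circular direction space.

Every directional signal in the model — head direction, allocentric and
egocentric goal direction, egocentric cue direction — is carried by a
population of units with Gaussian tuning curves on the circle,

    e_i = exp(-((theta_i - theta_input))^2 / sigma^2),

where the angular difference is wrapped to (-180, 180] and ``sigma`` is
the tuning width in degrees (10 by default, shared by all populations).
After encoding, zero-mean Gaussian noise is added and the population is
max-normalized so its strongest unit fires at exactly 1.  Decoding is
winner-take-all: the preferred angle of the most active unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np


class DegeneratePopulationError(ValueError):
    """Raised when a population carries no decodable signal."""


def wrap_angle(angle):
    """Wrap an angle (degrees) into (-180, 180].

    Accepts scalars or arrays; raises on non-finite input.
    """
    arr = np.asarray(angle, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap_angle requires finite input")
    wrapped = np.mod(arr, 360.0)
    wrapped = np.where(wrapped > 180.0, wrapped - 360.0, wrapped)
    if np.isscalar(angle) or arr.ndim == 0:
        return float(wrapped)
    return wrapped


def gaussian_tuning(preferred, input_angle, sigma: float):
    """Tuning-curve activation for a unit preferring ``preferred`` degrees.

    Maximal (1.0) when ``input_angle == preferred``; the difference is
    circular, so units near 0/360 behave like any other.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    delta = wrap_angle(np.asarray(preferred, dtype=float) - np.asarray(input_angle, dtype=float))
    out = np.exp(-(np.asarray(delta) ** 2) / sigma**2)
    if np.ndim(out) == 0:
        return float(out)
    return out


@dataclass
class CellPopulation:
    """Activities of N direction-tuned units.

    ``preferred_angles`` are in degrees (unit i prefers i*360/N for the
    standard construction); ``activities`` are dimensionless and lie in
    [0, 1] once normalized.
    """

    preferred_angles: np.ndarray
    activities: np.ndarray
    sigma: float

    def __post_init__(self):
        self.preferred_angles = np.asarray(self.preferred_angles, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.preferred_angles.shape != self.activities.shape:
            raise ValueError("preferred_angles and activities must have equal length")

    def __len__(self) -> int:
        return self.preferred_angles.size

    @property
    def is_degenerate(self) -> bool:
        return self.activities.size == 0 or float(np.max(self.activities)) <= 0.0

    def value_at(self, angle: float) -> float:
        """Activity of the unit whose preferred angle is circularly nearest."""
        if len(self) == 0:
            raise DegeneratePopulationError("empty population")
        idx = int(np.argmin(np.abs(wrap_angle(self.preferred_angles - angle))))
        return float(self.activities[idx])


@dataclass
class NoiseModel:
    """Additive activity noise shared by all populations of one run."""

    noise_sd: float = 0.05
    rng_seed: Optional[int] = None
    mode: str = "gaussian"  # "gaussian" | "literal" | "off"
    rng: np.random.Generator = field(default=None, repr=False)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.rng is None:
            self.rng = np.random.default_rng(self.rng_seed)

    def sample(self, activities: np.ndarray) -> np.ndarray:
        if self.mode == "off" or (self.mode == "gaussian" and self.noise_sd == 0.0):
            return np.zeros_like(activities)
        if self.mode == "gaussian":
            return self.rng.normal(0.0, self.noise_sd, size=activities.shape)
        if self.mode == "literal":
            # the uncorrected historical form: mean e_i, variance 5
            return self.rng.normal(activities, math.sqrt(5.0), size=activities.shape)
        raise ValueError(f"unknown noise mode: {self.mode}")


def encode_population(input_angle: float, sigma: float = 10.0, n_units: int = 360) -> CellPopulation:
    """Encode a direction into a fresh (noise-free) population.

    Unit i prefers ``i * 360 / n_units`` degrees.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    preferred = np.arange(n_units, dtype=float) * (360.0 / n_units)
    activities = gaussian_tuning(preferred, float(input_angle), sigma)
    return CellPopulation(preferred, np.atleast_1d(activities), sigma)


def add_noise_and_normalize(pop: CellPopulation, noise: Union[NoiseModel, None] = None) -> CellPopulation:
    """Add activity noise, clamp negatives to zero, divide by the maximum.

    Firing rates cannot be negative, so noise-driven negative values are
    clamped before normalization.  If nothing survives above zero the
    input was unencodable and a :class:`DegeneratePopulationError` is
    raised.
    """
    acts = pop.activities.astype(float, copy=True)
    if noise is not None:
        acts = acts + noise.sample(acts)
    acts = np.clip(acts, 0.0, None)
    peak = float(np.max(acts)) if acts.size else 0.0
    if peak <= 0.0:
        raise DegeneratePopulationError("all activities non-positive after noise")
    return CellPopulation(pop.preferred_angles.copy(), acts / peak, pop.sigma)


def population_peak(pop: CellPopulation) -> float:
    """Winner-take-all decode: preferred angle of the most active unit.

    Ties break toward the lowest preferred angle (argmax returns the
    first index and preferred angles are stored in increasing order).
    """
    if len(pop) == 0:
        raise DegeneratePopulationError("empty population")
    return float(pop.preferred_angles[int(np.argmax(pop.activities))])


def bearing(from_xy, to_xy) -> float:
    """Allocentric bearing (degrees, atan2 convention) of ``to`` from ``from``."""
    dx = float(to_xy[0]) - float(from_xy[0])
    dy = float(to_xy[1]) - float(from_xy[1])
    return wrap_angle(math.degrees(math.atan2(dy, dx)))


__all__ = [
    "CellPopulation",
    "NoiseModel",
    "DegeneratePopulationError",
    "wrap_angle",
    "gaussian_tuning",
    "encode_population",
    "add_noise_and_normalize",
    "population_peak",
    "bearing",
]
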