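"""Cognitive map: place cells, landmark-graph routes and the AGD code.

The hippocampus module holds a topological map of the environment —
landmarks with Cartesian coordinates joined by connection vectors that
carry distance and allocentric direction.  Localization is winner-take-
all: only the place cell nearest the agent is active.  Routes are
minimum-distance landmark sequences on the graph, and summing a route's
connection vectors yields the goal vector, whose direction is encoded in
a population of 360 allocentric goal direction (AGD) cells at 1 degree
spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .neural_coding import (
    CellPopulation,
    NoiseModel,
    add_noise_and_normalize,
    bearing,
    encode_population,
    wrap_angle,
)


class NoRouteError(ValueError):
    """The goal is unreachable from the start landmark."""


@dataclass(frozen=True)
class Landmark:
    id: str
    position: Tuple[float, float]
    is_goal: bool = False
    is_choice_point: bool = False


@dataclass
class GoalVector:
    distance: float
    direction: float  # allocentric degrees

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


class CognitiveMap:
    """Landmark graph with per-edge distance and allocentric direction.

    Edge distances always equal the Euclidean distance between endpoint
    positions (they are derived, never stored independently), and the
    direction of the reverse edge differs by 180 degrees by construction.
    """

    def __init__(self):
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------
    def add_landmark(self, landmark: Landmark) -> None:
        if landmark.id in self.graph:
            raise ValueError(f"duplicate landmark id: {landmark.id}")
        self.graph.add_node(landmark.id, landmark=landmark)

    def add_edge(self, id_a: str, id_b: str) -> None:
        for lid in (id_a, id_b):
            if lid not in self.graph:
                raise KeyError(f"unknown landmark: {lid}")
        self.graph.add_edge(id_a, id_b, distance=self.distance_between(id_a, id_b))

    # -- queries ------------------------------------------------------
    @property
    def landmarks(self) -> List[Landmark]:
        return [self.graph.nodes[n]["landmark"] for n in sorted(self.graph.nodes)]

    def landmark(self, lid: str) -> Landmark:
        return self.graph.nodes[lid]["landmark"]

    def position(self, lid: str) -> np.ndarray:
        return np.asarray(self.landmark(lid).position, dtype=float)

    def distance_between(self, id_a: str, id_b: str) -> float:
        return float(np.linalg.norm(self.position(id_a) - self.position(id_b)))

    def edge_direction(self, id_a: str, id_b: str) -> float:
        """Allocentric direction of the connection vector a -> b."""
        if not self.graph.has_edge(id_a, id_b):
            raise KeyError(f"no edge {id_a} -- {id_b}")
        return bearing(self.position(id_a), self.position(id_b))

    def goal_ids(self) -> List[str]:
        return [lm.id for lm in self.landmarks if lm.is_goal]


def active_place_cell(position, cmap: CognitiveMap) -> str:
    """Winner-take-all place cell: id of the nearest landmark.

    Ties break toward the lowest id.
    """
    landmarks = cmap.landmarks
    if not landmarks:
        raise ValueError("empty cognitive map")
    pos = np.asarray(position, dtype=float)
    best = min(landmarks, key=lambda lm: (float(np.linalg.norm(pos - np.asarray(lm.position))), lm.id))
    return best.id


def plan_route(cmap: CognitiveMap, start: str, goal: str) -> List[str]:
    """Minimum-total-distance landmark sequence from start to goal.

    Dijkstra distances (networkx) with a deterministic reconstruction:
    walking back from the goal, among all optimal predecessors the one
    with the lowest id is chosen.
    """
    for lid in (start, goal):
        if lid not in cmap.graph:
            raise KeyError(f"unknown landmark: {lid}")
    if start == goal:
        return [start]
    dist = nx.single_source_dijkstra_path_length(cmap.graph, start, weight="distance")
    if goal not in dist:
        raise NoRouteError(f"no route from {start} to {goal}")
    path = [goal]
    node = goal
    while node != start:
        candidates = [
            u
            for u in sorted(cmap.graph.neighbors(node))
            if u in dist
            and abs(dist[u] + cmap.graph.edges[u, node]["distance"] - dist[node]) <= 1e-9 * max(1.0, dist[node])
        ]
        node = candidates[0]
        path.append(node)
    return path[::-1]


def route_distance(cmap: CognitiveMap, route: Sequence[str]) -> float:
    return float(sum(cmap.distance_between(a, b) for a, b in zip(route[:-1], route[1:])))


def goal_vector(cmap: CognitiveMap, route: Sequence[str]) -> GoalVector:
    """Vector sum of the route's connection vectors.

    By the telescoping sum this equals the straight-line displacement
    from the first to the last landmark.  A single-element route returns
    (0, 0) by convention.
    """
    if len(route) == 0:
        raise ValueError("empty route")
    if len(route) == 1:
        return GoalVector(0.0, 0.0)
    start = cmap.position(route[0])
    end = cmap.position(route[-1])
    delta = end - start
    distance = float(np.linalg.norm(delta))
    if distance == 0.0:
        return GoalVector(0.0, 0.0)
    return GoalVector(distance, wrap_angle(math.degrees(math.atan2(delta[1], delta[0]))))


def agd_population(
    goal_direction: float,
    sigma: float = 10.0,
    n_units: int = 360,
    noise: Optional[NoiseModel] = None,
) -> CellPopulation:
    """Encode an allocentric goal direction in the AGD cell population."""
    pop = encode_population(goal_direction, sigma=sigma, n_units=n_units)
    return add_noise_and_normalize(pop, noise)


__all__ = [
    "Landmark",
    "GoalVector",
    "CognitiveMap",
    "NoRouteError",
    "active_place_cell",
    "plan_route",
    "route_distance",
    "goal_vector",
    "agd_population",
]
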