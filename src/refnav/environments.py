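"""Builders for the three experimental worlds.

Three environments are provided:

* a circular **blinking-light arena** — 32 cue lights on the boundary,
  exactly one active at a time; reaching the active light hands the
  blink to a randomly chosen other light;
* a **starmaze** — a central pentagonal ring corridor with five radial
  arms (ten numbered alleys, odd numbers are the arms), landmarks at
  ring junctions and arm ends, training start in alley 1, goal in alley
  7, probe start in alley 5;
* a **vista-space world** — eight rectangular regions joined by narrow
  corridors, region centroids acting as route landmarks, one goal cue
  per region.

Wall geometry is built with shapely (buffered corridor centrelines /
rectangle unions) and exposed as flat segment arrays for the collision
solver.  Every environment serializes to a plain YAML document and
reloads bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from shapely.geometry import LineString, MultiLineString, Point, Polygon, box
from shapely.ops import unary_union

from .hippocampus import CognitiveMap, Landmark
from .neural_coding import wrap_angle


@dataclass
class Cue:
    id: str
    position: Tuple[float, float]
    active: bool = True


@dataclass
class Environment:
    walls: np.ndarray  # (S, 2, 2) wall segments
    cues: List[Cue]
    regions: Dict[str, Polygon]
    map: CognitiveMap
    goal_id: str
    start_position: Tuple[float, float]
    start_heading: float
    metadata: dict = field(default_factory=dict)

    @property
    def active_cues(self) -> List[Cue]:
        return [c for c in self.cues if c.active]

    def cue(self, cue_id: str) -> Cue:
        for c in self.cues:
            if c.id == cue_id:
                return c
        raise KeyError(f"unknown cue: {cue_id}")


def _segments_of(geom) -> List[List[List[float]]]:
    """Flatten a shapely polygon (or multipolygon) boundary into segments."""
    segs: List[List[List[float]]] = []
    polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
    for poly in polys:
        rings = [poly.exterior, *poly.interiors]
        for ring in rings:
            coords = list(ring.coords)
            for a, b in zip(coords[:-1], coords[1:]):
                segs.append([[float(a[0]), float(a[1])], [float(b[0]), float(b[1])]])
    return segs


def _walls_array(segs: Sequence) -> np.ndarray:
    return np.asarray(segs, dtype=float).reshape(-1, 2, 2)


# ---------------------------------------------------------------------------
# blinking-light arena


def build_blinking_light_arena(
    radius: float = 5.0,
    n_lights: int = 32,
    rng: Optional[np.random.Generator] = None,
    wall_resolution: int = 64,
) -> Environment:
    """Circular arena with ``n_lights`` boundary cues, one active."""
    if n_lights < 2:
        raise ValueError("need at least two lights")
    rng = rng or np.random.default_rng()
    cues = []
    for i in range(n_lights):
        angle = math.radians(360.0 * i / n_lights)
        cues.append(Cue(f"light{i}", (radius * math.cos(angle), radius * math.sin(angle)), active=False))
    cues[int(rng.integers(n_lights))].active = True

    angles = np.linspace(0.0, 2.0 * math.pi, wall_resolution + 1)
    pts = np.stack([radius * np.cos(angles), radius * np.sin(angles)], axis=1)
    walls = np.stack([pts[:-1], pts[1:]], axis=1)

    cmap = CognitiveMap()  # HPC is disabled in this experiment; map kept empty
    return Environment(
        walls=walls,
        cues=cues,
        regions={},
        map=cmap,
        goal_id=next(c.id for c in cues if c.active),
        start_position=(0.0, 0.0),
        start_heading=0.0,
        metadata={"kind": "blinking_light", "radius": radius, "n_lights": n_lights},
    )


def advance_blinking_cue(
    env: Environment,
    agent_position,
    capture_radius: float,
    rng: np.random.Generator,
) -> bool:
    """Hand the blink to a random other light once the agent arrives.

    Returns True if the active cue switched.  The invariant "exactly one
    active cue" is checked on entry and preserved.
    """
    active = env.active_cues
    if len(active) != 1:
        raise ValueError(f"expected exactly one active cue, found {len(active)}")
    cue = active[0]
    pos = np.asarray(agent_position, dtype=float)
    if float(np.linalg.norm(pos - np.asarray(cue.position))) > capture_radius:
        return False
    others = [c for c in env.cues if c.id != cue.id]
    cue.active = False
    nxt = others[int(rng.integers(len(others)))]
    nxt.active = True
    env.goal_id = nxt.id
    return True


# ---------------------------------------------------------------------------
# starmaze


def _arm_angle(arm: int) -> float:
    """Allocentric angle of an odd-numbered arm (arm 1 at 90°, clockwise)."""
    j = (arm - 1) // 2
    return 90.0 - 72.0 * j


def build_starmaze(
    arm_length: float = 5.0,
    ring_radius: float = 5.0,
    alley_width: float = 1.0,
) -> Environment:
    """Pentagonal ring with five radial arms (ten numbered alleys).

    Odd alleys 1,3,5,7,9 are the arms (clockwise, arm 1 at the top);
    even alleys are the ring segments between consecutive arms.
    Landmarks sit at the five ring junctions (choice points) and five
    arm ends; training runs go from the alley-1 end to the goal at the
    alley-7 end, probe trials start at the alley-5 end.
    """
    if min(arm_length, ring_radius, alley_width) <= 0:
        raise ValueError("maze dimensions must be positive")
    arms = [1, 3, 5, 7, 9]
    junction = {a: np.array([ring_radius * math.cos(math.radians(_arm_angle(a))),
                             ring_radius * math.sin(math.radians(_arm_angle(a)))]) for a in arms}
    arm_end = {a: junction[a] * (ring_radius + arm_length) / ring_radius for a in arms}

    centerlines = []
    for a in arms:
        centerlines.append(LineString([junction[a], arm_end[a]]))
    ring_pairs = [(arms[i], arms[(i + 1) % 5]) for i in range(5)]
    for a, b in ring_pairs:
        centerlines.append(LineString([junction[a], junction[b]]))
    corridor = unary_union(MultiLineString(centerlines).buffer(alley_width / 2.0, quad_segs=8))
    walls = _walls_array(_segments_of(corridor))

    cmap = CognitiveMap()
    for a in arms:
        cmap.add_landmark(Landmark(f"j{a}", tuple(junction[a]), is_choice_point=True))
        cmap.add_landmark(Landmark(f"a{a}", tuple(arm_end[a]), is_goal=(a == 7)))
    for a in arms:
        cmap.add_edge(f"a{a}", f"j{a}")
    for a, b in ring_pairs:
        cmap.add_edge(f"j{a}", f"j{b}")

    # non-overlapping outer-arm regions used for trial classification
    regions: Dict[str, Polygon] = {}
    for a in arms:
        inner = junction[a] + (arm_end[a] - junction[a]) * 0.4
        regions[f"alley_{a}"] = LineString([inner, arm_end[a]]).buffer(alley_width / 2.0, cap_style="square")

    # distal allocentric cues outside the maze (scene dressing; the
    # allocentric strategy reads the cognitive map, not these)
    cue_r = ring_radius + arm_length + 5.0
    cues = [
        Cue(f"distal{k}", (cue_r * math.cos(math.radians(ang)), cue_r * math.sin(math.radians(ang))))
        for k, ang in enumerate((90.0, 210.0, 330.0))
    ]

    start = arm_end[5]
    heading = wrap_angle(_arm_angle(5) + 180.0)
    # replay path of the trained 1->7 sequence when started from alley 5
    # (the maze is 5-fold symmetric; rotating the trained route by the
    # start-arm offset gives the alley the replay terminates in)
    metadata = {
        "kind": "starmaze",
        "arm_length": arm_length,
        "ring_radius": ring_radius,
        "alley_width": alley_width,
        "train_start": "a1",
        "train_goal": "a7",
        "probe_start": "a5",
        "replay_path": ["a5", "j5", "j3", "j1", "a1"],
        # crossing the ring toward alley 1 = reaching the first ring
        # segment (alley 4) of the replay path; its midpoint is the sentinel
        "mixed_sentinel_xy": [float(v) for v in (junction[5] + junction[3]) / 2.0],
        "egocentric_terminal": "a1",
    }
    return Environment(
        walls=walls,
        cues=cues,
        regions=regions,
        map=cmap,
        goal_id="a7",
        start_position=tuple(start),
        start_heading=heading,
        metadata=metadata,
    )


def starmaze_pose(env: Environment, landmark_id: str) -> Tuple[Tuple[float, float], float]:
    """Pose at an arm-end landmark, heading inward along the arm."""
    arm = int(landmark_id[1:])
    pos = tuple(env.map.position(landmark_id))
    return pos, wrap_angle(_arm_angle(arm) + 180.0)


# ---------------------------------------------------------------------------
# vista-space world

DEFAULT_VISTA_LAYOUT: Dict[str, Tuple[int, int]] = {
    # 3x3 grid minus the top-right cell; region 4 bottom-left is the start,
    # region 5 is the "trap" (its only corridors lead sideways).
    "4": (0, 0), "5": (1, 0), "3": (2, 0),
    "9": (0, 1), "7": (1, 1), "2": (2, 1),
    "1": (0, 2), "6": (1, 2),
}

DEFAULT_VISTA_ADJACENCY: List[Tuple[str, str]] = [
    ("4", "5"), ("5", "3"), ("9", "7"), ("7", "2"), ("1", "6"),
    ("4", "9"), ("9", "1"), ("7", "6"), ("3", "2"),
]


def build_vista_world(
    layout: Optional[Dict[str, Tuple[int, int]]] = None,
    adjacency: Optional[List[Tuple[str, str]]] = None,
    region_size: float = 6.0,
    gap: float = 2.0,
    corridor_width: float = 1.0,
    blocked: Optional[List[Tuple[str, str]]] = None,
    remove_blocked_edges: bool = True,
    start_region: str = "4",
) -> Environment:
    """Grid of rectangular regions joined by narrow corridors.

    Region centroids become the route landmarks; every region carries
    one goal cue (placed at the centroid by default, re-randomized per
    trial by the experiment runner).  Corridors named in ``blocked`` are
    walled shut; their map edges are removed unless
    ``remove_blocked_edges`` is False.
    """
    layout = dict(layout or DEFAULT_VISTA_LAYOUT)
    adjacency = list(adjacency or DEFAULT_VISTA_ADJACENCY)
    blocked_set = {tuple(sorted(e)) for e in (blocked or [])}
    spacing = region_size + gap

    rects: Dict[str, Polygon] = {}
    centers: Dict[str, np.ndarray] = {}
    for rid, (col, row) in layout.items():
        x0, y0 = col * spacing, row * spacing
        rects[rid] = box(x0, y0, x0 + region_size, y0 + region_size)
        centers[rid] = np.array([x0 + region_size / 2.0, y0 + region_size / 2.0])

    import networkx as nx

    base = nx.Graph()
    base.add_nodes_from(layout)
    base.add_edges_from(adjacency)
    if not nx.is_connected(base):
        raise ValueError("vista layout is disconnected")

    corridor_polys = []
    open_edges = []
    for a, b in adjacency:
        if tuple(sorted((a, b))) in blocked_set:
            continue
        open_edges.append((a, b))
        ca, cb = centers[a], centers[b]
        mid = (ca + cb) / 2.0
        if abs(ca[0] - cb[0]) > abs(ca[1] - cb[1]):  # horizontal corridor
            corridor_polys.append(box(mid[0] - gap / 2.0 - 0.1, mid[1] - corridor_width / 2.0,
                                      mid[0] + gap / 2.0 + 0.1, mid[1] + corridor_width / 2.0))
        else:
            corridor_polys.append(box(mid[0] - corridor_width / 2.0, mid[1] - gap / 2.0 - 0.1,
                                      mid[0] + corridor_width / 2.0, mid[1] + gap / 2.0 + 0.1))

    walkable = unary_union(list(rects.values()) + corridor_polys)
    walls = _walls_array(_segments_of(walkable))

    cmap = CognitiveMap()
    for rid in sorted(layout):
        cmap.add_landmark(Landmark(f"c{rid}", tuple(centers[rid])))
    for a, b in adjacency:
        if remove_blocked_edges and tuple(sorted((a, b))) in blocked_set:
            continue
        cmap.add_edge(f"c{a}", f"c{b}")

    cues = [Cue(f"cue{rid}", tuple(centers[rid])) for rid in sorted(layout)]

    return Environment(
        walls=walls,
        cues=cues,
        regions=rects,
        map=cmap,
        goal_id="cue7",
        start_position=tuple(centers[start_region]),
        start_heading=90.0,
        metadata={
            "kind": "vista",
            "layout": {k: list(v) for k, v in layout.items()},
            "adjacency": [list(e) for e in adjacency],
            "blocked": [list(e) for e in sorted(blocked_set)],
            "region_size": region_size,
            "gap": gap,
            "corridor_width": corridor_width,
            "start_region": start_region,
        },
    )


def region_of(position, env: Environment) -> Optional[str]:
    """Id of the region polygon containing ``position`` (None if in a corridor)."""
    pt = Point(float(position[0]), float(position[1]))
    for rid in sorted(env.regions):
        if env.regions[rid].covers(pt):
            return rid
    return None


# ---------------------------------------------------------------------------
# serialization


def dump_environment(env: Environment) -> str:
    landmarks = [
        {
            "id": lm.id,
            "x": float(lm.position[0]),
            "y": float(lm.position[1]),
            "is_goal": lm.is_goal,
            "is_choice_point": lm.is_choice_point,
        }
        for lm in env.map.landmarks
    ]
    edges = sorted([sorted(e) for e in env.map.graph.edges])
    doc = {
        "walls": env.walls.tolist(),
        "cues": [{"id": c.id, "x": float(c.position[0]), "y": float(c.position[1]), "active": c.active} for c in env.cues],
        "regions": {rid: [[float(x), float(y)] for x, y in poly.exterior.coords] for rid, poly in env.regions.items()},
        "landmarks": landmarks,
        "edges": edges,
        "goal_id": env.goal_id,
        "start": {"x": float(env.start_position[0]), "y": float(env.start_position[1]), "heading": float(env.start_heading)},
        "metadata": env.metadata,
    }
    return yaml.safe_dump(doc, sort_keys=True)


def load_environment(text: str) -> Environment:
    doc = yaml.safe_load(text)
    cmap = CognitiveMap()
    for lm in doc["landmarks"]:
        cmap.add_landmark(
            Landmark(lm["id"], (lm["x"], lm["y"]), is_goal=lm["is_goal"], is_choice_point=lm["is_choice_point"])
        )
    for a, b in doc["edges"]:
        cmap.add_edge(a, b)
    regions = {rid: Polygon(coords) for rid, coords in doc["regions"].items()}
    return Environment(
        walls=np.asarray(doc["walls"], dtype=float).reshape(-1, 2, 2),
        cues=[Cue(c["id"], (c["x"], c["y"]), c["active"]) for c in doc["cues"]],
        regions=regions,
        map=cmap,
        goal_id=doc["goal_id"],
        start_position=(doc["start"]["x"], doc["start"]["y"]),
        start_heading=doc["start"]["heading"],
        metadata=doc["metadata"],
    )


__all__ = [
    "Cue",
    "Environment",
    "build_blinking_light_arena",
    "advance_blinking_cue",
    "build_starmaze",
    "starmaze_pose",
    "build_vista_world",
    "region_of",
    "dump_environment",
    "load_environment",
    "DEFAULT_VISTA_LAYOUT",
    "DEFAULT_VISTA_ADJACENCY",
]
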