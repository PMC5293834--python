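"""Plot helpers for trajectories, confidence traces and tuning surfaces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .environments import Environment
from .experiments import TrialLog


def plot_trajectory(log: TrialLog, env: Environment, ax=None, color_by_strategy: bool = True):
    """Trajectory over the wall map, optionally colored by active strategy."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for seg in env.walls:
        ax.plot(seg[:, 0], seg[:, 1], color="0.3", lw=1)
    xs = [r["x"] for r in log.records]
    ys = [r["y"] for r in log.records]
    if color_by_strategy:
        strategies = sorted({r["strategy"] for r in log.records})
        cmap = {s: f"C{i}" for i, s in enumerate(strategies)}
        for s in strategies:
            pts = [(r["x"], r["y"]) for r in log.records if r["strategy"] == s]
            arr = np.asarray(pts)
            ax.plot(arr[:, 0], arr[:, 1], ".", ms=2, color=cmap[s], label=s)
        ax.legend(fontsize=8)
    else:
        ax.plot(xs, ys, "-", lw=1)
    for cue in env.cues:
        ax.plot(*cue.position, "o", color="green" if cue.active else "gold", ms=5)
    ax.set_aspect("equal")
    return ax


def plot_confidences(log: TrialLog, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    conf_cols = [k for k in log.records[0] if k.startswith("conf_")]
    ts = [r["t"] for r in log.records]
    for col in conf_cols:
        ax.plot(ts, [r[col] for r in log.records], label=col.removeprefix("conf_"))
    ax.set_xlabel("time step")
    ax.set_ylabel("confidence")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    return ax


def plot_conjunctive_surface(surface_entry: dict, ax=None):
    """Heat map of a probed conjunctive-cell tuning surface."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    hd, ecd, surf = surface_entry["hd_grid"], surface_entry["ecd_grid"], surface_entry["surface"]
    im = ax.pcolormesh(ecd, hd, surf, shading="auto")
    ax.set_xlabel("egocentric cue direction (deg)")
    ax.set_ylabel("head direction (deg)")
    plt.colorbar(im, ax=ax, label="response")
    return ax


__all__ = ["plot_trajectory", "plot_confidences", "plot_conjunctive_surface"]
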