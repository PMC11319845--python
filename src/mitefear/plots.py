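"""Trajectory panel figures: per-replicate lines with the ensemble mean."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .engine import ReplicateSet

__all__ = ["trajectory_grid", "trajectory_grid_from_frame"]

_MAX_LINES = 250  # per-replicate lines drawn per panel (plotting cost cap)


def _panel(ax, trajectories: np.ndarray, label: str) -> None:
    n = trajectories.shape[0]
    shown = trajectories
    if n > _MAX_LINES:
        idx = np.linspace(0, n - 1, _MAX_LINES).astype(int)
        shown = trajectories[idx]
    days = np.arange(trajectories.shape[1])
    ax.plot(days, shown.T, color="black", lw=0.3, alpha=0.25)
    ax.plot(days, trajectories.mean(axis=0), color="red", lw=1.8)
    ax.set_title(f"Scenario {label}")
    ax.set_xlabel("day")
    ax.set_ylabel("adult flies")


def trajectory_grid(rep_sets: dict[str, ReplicateSet] | list[ReplicateSet]):
    """2 x 3 grid (one panel per scenario): black replicate trajectories,
    red ensemble mean."""
    if isinstance(rep_sets, dict):
        items = [(k, rep_sets[k].adult_trajectories) for k in sorted(rep_sets)]
    else:
        items = [(rs.scenario.id, rs.adult_trajectories) for rs in rep_sets]
    return _grid(items)


def trajectory_grid_from_frame(df: pd.DataFrame):
    """Same figure, built from a long-format trajectory table."""
    items = []
    for sid, group in df.groupby("scenario"):
        total = group["adults_uninfected"] + group["adults_infected"]
        wide = (
            group.assign(adults=total)
            .pivot(index="replicate", columns="day", values="adults")
            .to_numpy()
        )
        items.append((str(sid), wide))
    return _grid(items)


def _grid(items):
    ncols = 3 if len(items) > 2 else len(items)
    nrows = max(1, math.ceil(len(items) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.2 * ncols, 3.2 * nrows), squeeze=False
    )
    flat = axes.ravel()
    for ax, (label, traj) in zip(flat, items):
        _panel(ax, np.asarray(traj), label)
    for ax in flat[len(items):]:
        ax.set_visible(False)
    fig.tight_layout()
    return fig
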