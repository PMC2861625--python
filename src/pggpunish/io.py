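"""Serialization: trajectory CSV, text-grid snapshots, run manifests, PNG rendering.

Snapshots are plain text — one character per site from ``CDMI``, one line
per lattice row — human-diffable and sufficient to restart or render a
configuration.  Trajectories are CSV with header ``t,f_C,f_D,f_M,f_I``.
Manifests are JSON and contain everything needed to bit-reproduce a run.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .core import STRATEGY_CHARS, ModelParams, Strategy
from .dynamics import SimulationState, Trajectory

__all__ = [
    "RunManifest",
    "write_snapshot",
    "read_snapshot",
    "write_trajectory",
    "read_trajectory",
    "write_manifest",
    "read_manifest",
    "render_snapshot",
    "SNAPSHOT_COLORS",
]

# Color convention of the model's figures: C blue, D red, M green, I yellow.
SNAPSHOT_COLORS = {"C": "#1f4fd8", "D": "#d62728", "M": "#2ca02c", "I": "#f5d327"}

_CODE_OF = {ch: i for i, ch in enumerate(STRATEGY_CHARS)}


@dataclass
class RunManifest:
    """Everything needed to reproduce a run and interpret its outputs."""

    params: dict
    seed: Optional[int]
    topology: dict
    t_final: int
    stop_reason: str
    wall_time_s: float
    version: str = field(default=__version__)


def write_snapshot(state: Union[SimulationState, np.ndarray], L: int,
                   path: Union[str, Path]) -> None:
    """Write an L x L configuration as L lines of L characters from CDMI."""
    strategies = np.asarray(getattr(state, "strategies", state)).reshape(L, L)
    with open(path, "w") as fh:
        for row in strategies:
            fh.write("".join(STRATEGY_CHARS[int(s)] for s in row) + "\n")


def read_snapshot(path: Union[str, Path]) -> np.ndarray:
    """Read a text-grid snapshot back into an int8 strategy array (flat).

    Raises a ValueError naming line and column on malformed characters,
    and on ragged rows.
    """
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if width is None:
                width = len(line)
            elif len(line) != width:
                raise ValueError(
                    f"{path}: line {lineno} has length {len(line)}, expected {width}"
                )
            row = []
            for col, ch in enumerate(line, start=1):
                try:
                    row.append(_CODE_OF[ch])
                except KeyError:
                    raise ValueError(
                        f"{path}: invalid strategy character {ch!r} "
                        f"at line {lineno}, column {col}"
                    ) from None
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: empty snapshot")
    return np.array(rows, dtype=np.int8).ravel()


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write sampled strategy fractions as CSV (t, f_C, f_D, f_M, f_I)."""
    df = pd.DataFrame(traj.fractions, columns=["f_C", "f_D", "f_M", "f_I"])
    df.insert(0, "t", traj.times)
    df.to_csv(path, index=False)


def read_trajectory(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = ["t", "f_C", "f_D", "f_M", "f_I"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    return df


def write_manifest(manifest: RunManifest, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: Union[str, Path]) -> RunManifest:
    with open(path) as fh:
        return RunManifest(**json.load(fh))


def make_manifest(
    params: ModelParams,
    traj: Trajectory,
    topology: dict,
    wall_time_s: float,
) -> RunManifest:
    return RunManifest(
        params=asdict(params),
        seed=traj.seed,
        topology=topology,
        t_final=traj.t_final,
        stop_reason=traj.stop_reason,
        wall_time_s=wall_time_s,
    )


def render_snapshot(
    state: Union[SimulationState, np.ndarray],
    L: int,
    path: Union[str, Path],
    dpi: int = 150,
) -> None:
    """Render a snapshot to PNG with the standard color convention."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    strategies = np.asarray(getattr(state, "strategies", state)).reshape(L, L)
    cmap = ListedColormap([SNAPSHOT_COLORS[ch] for ch in STRATEGY_CHARS])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(strategies, cmap=cmap, vmin=-0.5, vmax=3.5, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
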