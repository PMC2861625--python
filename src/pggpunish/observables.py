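"""Measurements on states and trajectories.

Strategy fractions, extinction times, window-based phase classification,
same-strategy cluster sizes and interface density.  Cluster adjacency on a
lattice always uses the 4-neighbor (von Neumann) graph regardless of the
group neighborhood, matching how spatial domains are read off snapshots;
on non-lattice topologies the interaction graph itself is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import STRATEGY_CHARS, Strategy
from .dynamics import SimulationState, Trajectory
from .topology import Topology, build_lattice

__all__ = [
    "PhaseLabel",
    "strategy_fractions",
    "extinction_time",
    "classify_phase",
    "cluster_sizes",
    "interface_density",
    "cluster_size_table",
]


@dataclass(frozen=True)
class PhaseLabel:
    """Surviving-strategy set of a finished run.

    ``label`` lists the survivors in canonical C, D, M, I order joined by
    '+'.  ``neutral_voter`` marks the {C, M} survivor set with mu = 0: a
    transient neutral-drift coexistence that coarsens like the voter model
    (ultimately won by whichever strategy drifts to fixation) rather than
    a stable phase.
    """

    survivors: frozenset[Strategy]
    neutral_voter: bool = False

    def __post_init__(self) -> None:
        if not self.survivors:
            raise ValueError("survivor set must be nonempty")

    @property
    def label(self) -> str:
        return "+".join(
            STRATEGY_CHARS[s] for s in sorted(int(x) for x in self.survivors)
        )

    def __str__(self) -> str:  # pragma: no cover
        return self.label + (" (neutral voter, transient)" if self.neutral_voter else "")


def strategy_fractions(state: Union[SimulationState, np.ndarray]) -> np.ndarray:
    """Fractions of C, D, M, I among all players; sums to 1."""
    strategies = np.asarray(getattr(state, "strategies", state))
    counts = np.bincount(strategies.ravel(), minlength=4)
    return counts / strategies.size


def extinction_time(traj: Trajectory, s: Strategy) -> Optional[int]:
    """First iteration at which strategy ``s`` had count zero, or None.

    Well defined as a final event only for mu = 0 runs, where extinction
    is absorbing.
    """
    return traj.extinctions[Strategy(s)]


def classify_phase(traj: Trajectory, window: int) -> PhaseLabel:
    """Classify a finished run by the strategies alive throughout the final window.

    ``window`` is in iterations: all samples with ``t >= t_final - window``
    must show a nonzero count for a strategy to count as surviving (strict
    count > 0; with mu = 0 extinctions are absorbing so this equals
    survival at the final sample).
    """
    if window <= 0:
        raise ValueError(f"window must be a positive number of iterations, got {window}")
    sel = traj.times >= traj.times[-1] - window
    alive = (traj.counts[sel] > 0).all(axis=0)
    survivors = frozenset(Strategy(s) for s in range(4) if alive[s])
    neutral = traj.params.mu == 0 and survivors == {Strategy.C, Strategy.M}
    return PhaseLabel(survivors=survivors, neutral_voter=neutral)


def _cluster_adjacency(strategies: np.ndarray, topo: Topology) -> coo_matrix:
    """Sparse adjacency restricted to same-strategy pairs."""
    if topo.kind == "lattice" and topo.L is not None and topo.spec_name != "vonNeumann":
        topo = build_lattice(topo.L, "vonNeumann")
    n, k = topo.n_players, topo.degree
    rows = np.repeat(np.arange(n), k)
    cols = topo.neighbors.ravel()
    same = strategies[rows] == strategies[cols]
    return coo_matrix(
        (np.ones(int(same.sum()), dtype=np.int8), (rows[same], cols[same])),
        shape=(n, n),
    )


def cluster_sizes(
    state: Union[SimulationState, np.ndarray], topo: Topology
) -> dict[Strategy, list[int]]:
    """Connected same-strategy components, grouped by strategy.

    Sizes across all strategies partition the player set.  Lattices use
    4-neighbor adjacency with periodic wrap-around.
    """
    strategies = np.asarray(getattr(state, "strategies", state))
    n_comp, labels = connected_components(
        _cluster_adjacency(strategies, topo), directed=False
    )
    sizes = np.bincount(labels, minlength=n_comp)
    # representative member per component gives the component's strategy
    rep = np.zeros(n_comp, dtype=np.int64)
    rep[labels] = np.arange(len(labels))
    out: dict[Strategy, list[int]] = {Strategy(s): [] for s in range(4)}
    for comp in range(n_comp):
        out[Strategy(int(strategies[rep[comp]]))].append(int(sizes[comp]))
    for s in out:
        out[s].sort(reverse=True)
    return out


def cluster_size_table(
    state: Union[SimulationState, np.ndarray], topo: Topology
) -> pd.DataFrame:
    """Cluster sizes as a tidy table (strategy, size), for CSV export."""
    rows = [
        {"strategy": s.char, "size": size}
        for s, sizes in cluster_sizes(state, topo).items()
        for size in sizes
    ]
    return pd.DataFrame(rows, columns=["strategy", "size"])


def interface_density(
    state: Union[SimulationState, np.ndarray], topo: Topology
) -> float:
    """Fraction of edges joining unlike strategies; 0 iff uniform.

    Coexistence in this model is governed by payoff balance at cluster
    interfaces, so this is the natural order parameter for coarsening.
    """
    strategies = np.asarray(getattr(state, "strategies", state))
    n, k = topo.n_players, topo.degree
    rows = np.repeat(np.arange(n), k)
    cols = topo.neighbors.ravel()
    unlike = strategies[rows] != strategies[cols]
    # every undirected edge appears twice in the neighbor table
    return float(unlike.sum() / (n * k))
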