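"""Payoff accounting for the four-strategy public goods game with punishment.

Four behavioral strategies interact in overlapping groups of size ``G``:

* **C** (cooperator) contributes 1 to the common pool, does not punish;
* **D** (defector) contributes nothing, does not punish;
* **M** (moralist) contributes 1 and punishes every defecting partner;
* **I** (immoralist) contributes nothing but punishes defecting partners.

The pooled contributions of a group are multiplied by the synergy factor
``r`` and split equally among all ``G`` members.  Every defecting player
(D or I) is fined ``beta/(G-1)`` per punishing partner, and every punishing
player (M or I) pays a cost ``gamma/(G-1)`` per defecting partner.  The
``1/(G-1)`` scaling makes fines and costs comparable across group sizes.

With ``n_C, n_D, n_M, n_I`` the strategy counts among a focal player's
``G-1`` partners and ``c`` the number of contributors in the group
(including the focal player if cooperative), the payoffs are::

    P_C = r*c/G - 1
    P_D = r*c/G - beta*(n_M + n_I)/(G - 1)
    P_M = P_C - gamma*(n_D + n_I)/(G - 1)
    P_I = P_D - gamma*(n_D + n_I)/(G - 1)

These satisfy the defining dominance relations: an immoralist never earns
more than a defector with the same partners (equality only when no partner
defects), a moralist never earns more than a cooperator (same condition),
and a cooperator beats a defector when the fine ``beta`` is large enough.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import TYPE_CHECKING, Union

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .dynamics import SimulationState
    from .topology import Topology

__all__ = [
    "Strategy",
    "ModelParams",
    "GroupComposition",
    "group_payoff",
    "total_payoff",
    "STRATEGY_CHARS",
    "IS_COOPERATIVE",
    "IS_DEFECTING",
    "IS_PUNISHING",
]


class Strategy(IntEnum):
    """The four behavioral strategies, in canonical C, D, M, I order."""

    C = 0
    D = 1
    M = 2
    I = 3

    @property
    def cooperative(self) -> bool:
        """True for the contributing strategies C and M."""
        return self in (Strategy.C, Strategy.M)

    @property
    def defecting(self) -> bool:
        """True for the non-contributing strategies D and I."""
        return not self.cooperative

    @property
    def punishing(self) -> bool:
        """True for the strategies that punish defectors: M and I."""
        return self in (Strategy.M, Strategy.I)

    @property
    def char(self) -> str:
        return STRATEGY_CHARS[self]


STRATEGY_CHARS = "CDMI"

# Boolean lookup tables indexed by integer strategy code, shared with the
# compiled kernel and with vectorized observables.
IS_COOPERATIVE = np.array([True, False, True, False])
IS_DEFECTING = np.array([False, True, False, True])
IS_PUNISHING = np.array([False, False, True, True])


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the game and its imitation dynamics.

    Parameters
    ----------
    r : float
        Synergy factor multiplying the pooled contributions (> 0).  For
        ``r < G`` defection is individually optimal in a single well-mixed
        group.
    beta : float
        Punishment fine, in payoff units (>= 0).  Each defecting player
        loses ``beta/(G-1)`` per punishing partner.
    gamma : float
        Punishment cost, in payoff units (>= 0).  Each punishing player
        pays ``gamma/(G-1)`` per defecting partner.
    K : float
        Imitation noise of the Fermi rule (> 0).  ``K -> 0`` gives
        deterministic imitation of better payoffs, ``K -> inf`` random
        copying.
    mu : float
        Strategy mutation probability per elementary update (in [0, 1]).
    G : int
        Group size: the focal player plus its ``G - 1`` interaction
        partners (>= 2).  Must equal ``1 + degree`` of the topology in use.
    """

    r: float
    beta: float = 0.0
    gamma: float = 0.0
    K: float = 0.5
    mu: float = 0.0
    G: int = 5

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError(f"synergy factor r must be > 0, got {self.r}")
        if self.beta < 0:
            raise ValueError(f"punishment fine beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"punishment cost gamma must be >= 0, got {self.gamma}")
        if self.K <= 0:
            raise ValueError(f"imitation noise K must be > 0, got {self.K}")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mutation rate mu must be in [0, 1], got {self.mu}")
        if int(self.G) != self.G or self.G < 2:
            raise ValueError(f"group size G must be an integer >= 2, got {self.G}")


@dataclass(frozen=True)
class GroupComposition:
    """Strategy counts among the G-1 partners of a focal player.

    The focal player itself is *not* counted.
    """

    nC: int
    nD: int
    nM: int
    nI: int

    def __post_init__(self) -> None:
        for name in ("nC", "nD", "nM", "nI"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n_partners(self) -> int:
        return self.nC + self.nD + self.nM + self.nI

    @property
    def contributors(self) -> int:
        """Contributing partners (C and M)."""
        return self.nC + self.nM

    @property
    def punishers(self) -> int:
        """Punishing partners (M and I)."""
        return self.nM + self.nI

    @property
    def defectors(self) -> int:
        """Defecting partners (D and I)."""
        return self.nD + self.nI


def group_payoff(s: Strategy, comp: GroupComposition, params: ModelParams) -> float:
    """Payoff of a focal player with strategy ``s`` in a single group.

    Pure function of the group composition: contributions are pooled,
    multiplied by ``r`` and split ``G`` ways; fines hit defecting players,
    costs hit punishing players, both scaled by ``1/(G-1)``.  The focal
    player never fines or pays for itself.

    Raises
    ------
    ValueError
        If ``comp`` does not describe exactly ``G - 1`` partners.
    """
    s = Strategy(s)
    G = params.G
    if comp.n_partners != G - 1:
        raise ValueError(
            f"composition has {comp.n_partners} partners, expected G-1 = {G - 1}"
        )
    c = comp.contributors + (1 if s.cooperative else 0)
    payoff = params.r * c / G
    if s.cooperative:
        payoff -= 1.0
    if s.defecting:
        payoff -= params.beta * comp.punishers / (G - 1)
    if s.punishing:
        payoff -= params.gamma * comp.defectors / (G - 1)
    return payoff


def total_payoff(
    site: int,
    state: Union["SimulationState", np.ndarray],
    topo: "Topology",
    params: ModelParams,
) -> float:
    """Overall payoff of ``site``: the sum over all groups it belongs to.

    On the lattice a player belongs to ``1 + degree`` groups — the one it
    centers plus the group centered on each neighbor — and plays the public
    goods game in every one of them on the *current* configuration.

    ``state`` may be a :class:`~pggpunish.dynamics.SimulationState` or a
    bare strategy array.
    """
    strategies = np.asarray(getattr(state, "strategies", state))
    if params.G != topo.degree + 1:
        raise ValueError(
            f"params.G = {params.G} inconsistent with topology degree "
            f"{topo.degree} (need G = degree + 1)"
        )
    if not 0 <= site < topo.n_players:
        raise IndexError(f"site {site} out of range for {topo.n_players} players")
    s = Strategy(int(strategies[site]))
    total = 0.0
    for center in (site, *topo.neighbors[site]):
        members = [int(center), *(int(m) for m in topo.neighbors[center])]
        partners = [m for m in members if m != site]
        counts = np.bincount(strategies[partners], minlength=4)
        comp = GroupComposition(*(int(n) for n in counts))
        total += group_payoff(s, comp, params)
    return total
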