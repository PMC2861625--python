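"""Independent brute-force oracles used across the test modules.

These score groups by explicit member-by-member bookkeeping (list the
members, pool the contributions, split, apply fines and costs one partner
at a time) and never call the package's closed-form payoff expressions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from pggpunish import Strategy, build_group_map
from pggpunish.core import ModelParams
from pggpunish.topology import Topology

COOPERATIVE = {Strategy.C, Strategy.M}
PUNISHING = {Strategy.M, Strategy.I}
DEFECTING = {Strategy.D, Strategy.I}


def oracle_group_payoff(
    focal: Strategy, partners: Sequence[Strategy], params: ModelParams
) -> float:
    """Score one group explicitly: pool, split, then per-partner fines/costs."""
    members = [Strategy(focal), *(Strategy(p) for p in partners)]
    G = len(members)
    assert G == params.G
    pool = sum(1 for m in members if m in COOPERATIVE) * params.r
    payoff = pool / G
    if members[0] in COOPERATIVE:
        payoff -= 1.0  # own contribution
    for p in members[1:]:
        if members[0] in DEFECTING and p in PUNISHING:
            payoff -= params.beta / (G - 1)
        if members[0] in PUNISHING and p in DEFECTING:
            payoff -= params.gamma / (G - 1)
    return payoff


def oracle_total_payoff(
    site: int, strategies: np.ndarray, topo: Topology, params: ModelParams
) -> float:
    """Enumerate every group the player belongs to and score each explicitly."""
    gmap = build_group_map(topo)
    total = 0.0
    for center in gmap.groups_of(site):
        members = gmap.members(center)
        assert site in members
        partners = [Strategy(int(strategies[m])) for m in members if m != site]
        total += oracle_group_payoff(Strategy(int(strategies[site])), partners, params)
    return total


def all_compositions(n_partners: int):
    """Every (nC, nD, nM, nI) with the given partner total."""
    for nC in range(n_partners + 1):
        for nD in range(n_partners + 1 - nC):
            for nM in range(n_partners + 1 - nC - nD):
                yield (nC, nD, nM, n_partners - nC - nD - nM)


def partners_of(comp) -> list[Strategy]:
    nC, nD, nM, nI = comp
    return (
        [Strategy.C] * nC + [Strategy.D] * nD + [Strategy.M] * nM + [Strategy.I] * nI
    )
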