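"""Numba-compiled hot loop for the lattice simulation.

Strategy codes follow :mod:`pggpunish.core`: C=0, D=1, M=2, I=3.  The
kernel keeps its own Mersenne-Twister stream (numba's ``np.random``),
seeded via :func:`seed_rng`; draws occur in the documented order
(focal site, neighbor index, adoption uniform, mutation uniform, mutant
strategy).  Updates in which focal and neighbor already share a strategy
are short-circuited: the adoption event would be a no-op, so neither
payoffs nor the adoption uniform are computed (mutation draws still
happen when mu > 0).
"""

import numpy as np
from numba import njit

_IS_COOP = np.array([1, 0, 1, 0], dtype=np.int64)
_IS_DEF = np.array([0, 1, 0, 1], dtype=np.int64)
_IS_PUN = np.array([0, 0, 1, 1], dtype=np.int64)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def total_payoff(strat, neigh, x, r, beta, gamma):
    """Sum of group payoffs of player x over the 1+degree groups it is in."""
    k = neigh.shape[1]
    G = k + 1
    sx = strat[x]
    cx = _IS_COOP[sx]
    dx = _IS_DEF[sx]
    px = _IS_PUN[sx]
    total = 0.0
    for gi in range(G):
        c = x if gi == k else neigh[x, gi]
        sc = strat[c]
        nco = _IS_COOP[sc]
        npu = _IS_PUN[sc]
        nde = _IS_DEF[sc]
        for j in range(k):
            sm = strat[neigh[c, j]]
            nco += _IS_COOP[sm]
            npu += _IS_PUN[sm]
            nde += _IS_DEF[sm]
        # counts above include the focal player; partner counts subtract it
        total += r * nco / G - cx
        if dx == 1:
            total -= beta * (npu - px) / k
        if px == 1:
            total -= gamma * (nde - dx) / k
    return total


@njit(cache=True)
def run_iterations(strat, neigh, counts, n_iters, t0, r, beta, gamma, K, mu,
                   out_counts, first_zero, stop_on_single):
    """Advance n_iters Monte Carlo steps of n_players elementary updates.

    Mutates ``strat`` and ``counts`` in place; writes per-iteration strategy
    counts to ``out_counts`` and first-extinction iterations to
    ``first_zero`` (-1 while alive).  Returns the number of iterations
    actually executed (early exit when a single strategy remains and
    ``stop_on_single`` is set).
    """
    n = strat.shape[0]
    k = neigh.shape[1]
    for it in range(n_iters):
        t_now = t0 + it + 1
        for _ in range(n):
            x = np.random.randint(0, n)
            y = neigh[x, np.random.randint(0, k)]
            sx = strat[x]
            sy = strat[y]
            new = sy
            if sx != sy:
                pi_x = total_payoff(strat, neigh, x, r, beta, gamma)
                pi_y = total_payoff(strat, neigh, y, r, beta, gamma)
                w = 1.0 / (1.0 + np.exp((pi_y - pi_x) / K))
                if np.random.random() < w:
                    new = sx
            if mu > 0.0 and np.random.random() < mu:
                new = np.random.randint(0, 4)
            if new != sy:
                strat[y] = new
                counts[sy] -= 1
                counts[new] += 1
                if counts[sy] == 0 and first_zero[sy] < 0:
                    first_zero[sy] = t_now
        for s in range(4):
            out_counts[it, s] = counts[s]
        if stop_on_single:
            alive = 0
            for s in range(4):
                if counts[s] > 0:
                    alive += 1
            if alive == 1:
                return it + 1
    return n_iters
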