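"""Well-mixed baseline: expected payoffs and replicator dynamics.

With well-mixed interactions every player's G-1 partners are an i.i.d.
sample from the population frequencies x = (x_C, x_D, x_M, x_I).  Because
each payoff is linear in the partner counts, the expected payoffs have the
closed form

    E[P_C] = r*((G-1)*(x_C + x_M) + 1)/G - 1
    E[P_D] = r*(G-1)*(x_C + x_M)/G - beta*(x_M + x_I)
    E[P_M] = E[P_C] - gamma*(x_D + x_I)
    E[P_I] = E[P_D] - gamma*(x_D + x_I)

so E[P_C] >= E[P_M] and E[P_D] >= E[P_I] everywhere (strictly when
defecting strategies are present): in the mean field second-order
free-riding always beats punishment, and defectors win from generic
initial conditions — the contrast that motivates the spatial model.

The deterministic dynamics is the replicator equation
``dx_s/dt = x_s (E[P_s] - avg)``; a finite-population imitation simulator
with randomly drawn partners is provided as a stochastic cross-check.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .core import IS_COOPERATIVE, IS_DEFECTING, IS_PUNISHING, ModelParams, Strategy
from .dynamics import imitation_probability

__all__ = [
    "as_simplex",
    "expected_payoffs",
    "replicator_trajectory",
    "simulate_wellmixed",
]


def as_simplex(x: Sequence[float], tol: float = 1e-9) -> np.ndarray:
    """Validate and return a frequency vector on the 3-simplex."""
    x = np.asarray(x, dtype=float)
    if x.shape != (4,):
        raise ValueError(f"expected 4 strategy frequencies, got shape {x.shape}")
    if (x < -tol).any() or abs(x.sum() - 1.0) > tol:
        raise ValueError(f"not a point on the simplex: {x} (sum {x.sum()})")
    return np.clip(x, 0.0, None) / np.clip(x, 0.0, None).sum()


def expected_payoffs(x: Sequence[float], params: ModelParams) -> np.ndarray:
    """Exact expected payoffs (C, D, M, I) over random groups drawn from x."""
    x = as_simplex(x)
    G = params.G
    coop = float(x[Strategy.C] + x[Strategy.M])
    pun = float(x[Strategy.M] + x[Strategy.I])
    dfc = float(x[Strategy.D] + x[Strategy.I])
    p_c = params.r * ((G - 1) * coop + 1) / G - 1
    p_d = params.r * (G - 1) * coop / G - params.beta * pun
    p_m = p_c - params.gamma * dfc
    p_i = p_d - params.gamma * dfc
    return np.array([p_c, p_d, p_m, p_i])


def replicator_trajectory(
    x0: Sequence[float],
    params: ModelParams,
    horizon: float = 500.0,
    n_points: int = 201,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate the replicator equation from ``x0`` up to ``horizon``.

    Returns a DataFrame with columns ``t, f_C, f_D, f_M, f_I`` (same shape
    as spatial trajectory exports).  The drift is renormalized onto the
    simplex at every evaluation; the sum of frequencies is conserved to
    integrator tolerance.
    """
    x0 = as_simplex(x0)

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, 0.0, None)
        s = x.sum()
        if s > 0:
            x = x / s
        p = expected_payoffs_unchecked(x, params)
        return x * (p - x @ p)

    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        x0,
        t_eval=np.linspace(0.0, float(horizon), n_points),
        rtol=rtol,
        atol=atol,
        method="LSODA",
    )
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    out = pd.DataFrame(sol.y.T, columns=["f_C", "f_D", "f_M", "f_I"])
    out.insert(0, "t", sol.t)
    return out


def expected_payoffs_unchecked(x: np.ndarray, params: ModelParams) -> np.ndarray:
    """Expected payoffs without simplex validation (ODE right-hand side)."""
    G = params.G
    coop = x[0] + x[2]
    p_c = params.r * ((G - 1) * coop + 1) / G - 1
    p_d = params.r * (G - 1) * coop / G - params.beta * (x[2] + x[3])
    cost = params.gamma * (x[1] + x[3])
    return np.array([p_c, p_d, p_c - cost, p_d - cost])


def simulate_wellmixed(
    n: int,
    params: ModelParams,
    t_max: int,
    seed: Optional[int] = None,
    x0: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Finite-population well-mixed imitation dynamics (stochastic cross-check).

    Each elementary update draws a focal player and a random *other*
    player; each evaluates its payoff in one group of G-1 partners drawn
    uniformly from the rest of the population, and the second player
    imitates the first with the Fermi probability.  One iteration is n
    updates.  Returns per-iteration fractions with the usual columns.
    """
    rng = np.random.default_rng(seed)
    if x0 is None:
        strategies = rng.integers(0, 4, size=n).astype(np.int8)
    else:
        x0 = as_simplex(x0)
        strategies = rng.choice(4, size=n, p=x0).astype(np.int8)

    coop = IS_COOPERATIVE.astype(float)
    dfc = IS_DEFECTING.astype(float)
    pun = IS_PUNISHING.astype(float)
    Gm1 = params.G - 1

    def one_payoff(player: int) -> float:
        partners = rng.choice(n - 1, size=Gm1, replace=False)
        partners[partners >= player] += 1
        ps = strategies[partners]
        s = int(strategies[player])
        c = coop[ps].sum() + coop[s]
        pay = params.r * c / params.G - coop[s]
        pay -= dfc[s] * params.beta * pun[ps].sum() / Gm1
        pay -= pun[s] * params.gamma * dfc[ps].sum() / Gm1
        return float(pay)

    rows = [np.bincount(strategies, minlength=4) / n]
    for _ in range(t_max):
        for _ in range(n):
            x = int(rng.integers(n))
            y = int(rng.integers(n - 1))
            if y >= x:
                y += 1
            if strategies[x] == strategies[y]:
                continue
            w = imitation_probability(one_payoff(x), one_payoff(y), params.K)
            if rng.random() < w:
                strategies[y] = strategies[x]
        rows.append(np.bincount(strategies, minlength=4) / n)
    out = pd.DataFrame(rows, columns=["f_C", "f_D", "f_M", "f_I"])
    out.insert(0, "t", np.arange(len(rows)))
    return out
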