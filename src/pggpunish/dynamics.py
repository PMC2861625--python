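"""Stochastic evolution by noisy imitation (Fermi rule) with random sequential updates.

One *iteration* (Monte Carlo step) consists of ``n_players`` elementary
updates.  In each elementary update a focal player ``x`` is drawn uniformly,
one of its neighbors ``y`` is drawn uniformly, and ``y`` adopts ``x``'s
strategy with the Fermi probability

    w = 1 / (1 + exp((Pi_y - Pi_x) / K)),

where ``Pi`` are the overall payoffs summed over all groups a player
belongs to, freshly computed from the live configuration.  With
probability ``mu`` the updating player's resulting strategy is then
replaced by a uniformly random one.  Only the chosen neighbor may change
strategy in an elementary update.

Two engines are provided: a compiled numba kernel (default, used for
production lattices) and a pure-python reference implementation built on
:func:`pggpunish.core.total_payoff` (small systems, oracle tests).  Both
are bit-reproducible given their seeds; both short-circuit updates where
focal and neighbor already share a strategy, which leaves the law of the
process unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.special import expit

from . import _kernel, core
from .core import ModelParams, Strategy
from .topology import GroupMap, Topology, build_lattice

__all__ = [
    "SimulationState",
    "RunConfig",
    "Trajectory",
    "UpdateEvent",
    "imitation_probability",
    "initialize_uniform",
    "elementary_update",
    "run",
    "simulate",
]


@dataclass
class SimulationState:
    """Per-site strategies plus the iteration counter and the RNG stream."""

    strategies: np.ndarray  # int8 codes, one per player
    t: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def __post_init__(self) -> None:
        self.strategies = np.ascontiguousarray(self.strategies, dtype=np.int8)

    @property
    def n_players(self) -> int:
        return self.strategies.shape[0]

    def counts(self) -> np.ndarray:
        """Strategy counts in canonical C, D, M, I order."""
        return np.bincount(self.strategies, minlength=4)

    def copy(self) -> "SimulationState":
        return SimulationState(self.strategies.copy(), self.t, self.rng)


@dataclass(frozen=True)
class RunConfig:
    """Length, sampling and reproducibility of a run."""

    t_max: int
    stop_on_absorbing: bool = True
    record_every: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.t_max < 0:
            raise ValueError(f"t_max must be >= 0, got {self.t_max}")
        if self.record_every < 1:
            raise ValueError(f"record_every must be >= 1, got {self.record_every}")


@dataclass
class Trajectory:
    """Sampled strategy counts over a run, plus extinction events.

    ``times[i]`` is the iteration of sample ``i`` (the initial configuration
    is sample 0); ``counts[i]`` the four strategy counts at that moment.
    ``extinctions`` maps each strategy to the first iteration at which its
    count reached zero, or ``None`` if it never did (final with mu = 0,
    where extinction is absorbing).
    """

    times: np.ndarray
    counts: np.ndarray
    n_players: int
    extinctions: dict[Strategy, Optional[int]]
    stop_reason: str
    params: ModelParams
    seed: Optional[int] = None

    @property
    def fractions(self) -> np.ndarray:
        """Strategy fractions, shape (n_samples, 4), rows sum to 1."""
        return self.counts / self.n_players

    @property
    def final_counts(self) -> np.ndarray:
        return self.counts[-1]

    @property
    def t_final(self) -> int:
        return int(self.times[-1])

    def survivors(self) -> frozenset[Strategy]:
        """Strategies with nonzero count at the last sample."""
        return frozenset(Strategy(s) for s in range(4) if self.final_counts[s] > 0)

    @property
    def neutral_voter_regime(self) -> bool:
        """True when only the two cooperative strategies remain with mu = 0.

        C and M then earn identical payoffs everywhere, the Fermi
        probability is exactly 1/2, and the dynamics reduces to the
        unbiased voter model (slow neutral coarsening).
        """
        return self.params.mu == 0 and self.survivors() == {Strategy.C, Strategy.M}


@dataclass(frozen=True)
class UpdateEvent:
    """Record of one elementary update (who was drawn, what changed)."""

    x: int
    y: int
    old: Strategy
    new: Strategy
    adopted: bool
    mutated: bool

    @property
    def changed(self) -> bool:
        return self.old != self.new


def imitation_probability(
    P_x: Union[float, np.ndarray], P_y: Union[float, np.ndarray], K: float
) -> Union[float, np.ndarray]:
    """Fermi probability that neighbor y imitates focal player x.

    ``w = 1 / (1 + exp((P_y - P_x) / K))``: monotone increasing in
    ``P_x - P_y``, exactly 1/2 at equal payoffs, a step function as
    ``K -> 0`` and 1/2 everywhere as ``K -> inf``.
    """
    if K <= 0:
        raise ValueError(f"noise K must be > 0, got {K}")
    w = expit((np.asarray(P_x) - np.asarray(P_y)) / K)
    return float(w) if np.ndim(w) == 0 else w


def initialize_uniform(
    topo: Topology,
    seed: Optional[int] = None,
    balanced: bool = False,
    strategies: Sequence[Strategy] = (Strategy.C, Strategy.D, Strategy.M, Strategy.I),
) -> SimulationState:
    """Random initial configuration, each strategy uniform in space.

    By default each site independently receives one of the listed
    strategies with equal probability (expected fraction 1/len each).  In
    ``balanced`` mode the assignment is an exact random permutation with
    identical counts per strategy, which requires ``n_players`` divisible
    by the number of strategies.
    """
    rng = np.random.default_rng(seed)
    codes = np.array([int(s) for s in strategies], dtype=np.int8)
    n = topo.n_players
    if balanced:
        if n % len(codes) != 0:
            raise ValueError(
                f"balanced init needs n_players ({n}) divisible by {len(codes)}"
            )
        grid = np.repeat(codes, n // len(codes))
        rng.shuffle(grid)
    else:
        grid = codes[rng.integers(0, len(codes), size=n)]
    return SimulationState(grid, t=0, rng=rng)


def elementary_update(
    state: SimulationState,
    topo: Topology,
    gmap: Optional[GroupMap],
    params: ModelParams,
) -> UpdateEvent:
    """One elementary update of the pure-python engine (mutates ``state``).

    Draw order from ``state.rng``: focal site, neighbor index, adoption
    uniform (skipped when focal and neighbor strategies coincide),
    mutation uniform and mutant strategy (only when mu > 0).
    """
    rng = state.rng
    x = int(rng.integers(topo.n_players))
    j = int(rng.integers(topo.degree))
    y = int(topo.neighbors[x, j])
    sx = Strategy(int(state.strategies[x]))
    sy = Strategy(int(state.strategies[y]))
    new = sy
    adopted = False
    if sx != sy:
        pi_x = core.total_payoff(x, state, topo, params)
        pi_y = core.total_payoff(y, state, topo, params)
        w = imitation_probability(pi_x, pi_y, params.K)
        if rng.random() < w:
            new = sx
            adopted = True
    mutated = False
    if params.mu > 0 and rng.random() < params.mu:
        new = Strategy(int(rng.integers(4)))
        mutated = True
    if new != sy:
        state.strategies[y] = int(new)
    return UpdateEvent(x=x, y=y, old=sy, new=new, adopted=adopted, mutated=mutated)


def _record_indices(n_done: int, record_every: int) -> np.ndarray:
    """Indices (0-based, into per-iteration rows) to keep as samples."""
    if n_done == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.arange(record_every - 1, n_done, record_every)
    if len(idx) == 0 or idx[-1] != n_done - 1:
        idx = np.append(idx, n_done - 1)
    return idx


def run(
    initial: SimulationState,
    cfg: RunConfig,
    topo: Topology,
    gmap: Optional[GroupMap] = None,
    params: Optional[ModelParams] = None,
    engine: str = "numba",
) -> Trajectory:
    """Evolve ``initial`` (in place) for up to ``cfg.t_max`` iterations.

    Stops early only when a *single* strategy remains (and
    ``cfg.stop_on_absorbing``).  A state containing only C and M with
    mu = 0 is the neutral voter regime: coarsening continues, so the run
    is not stopped; the trajectory flags the regime instead.
    Fully reproducible given the seeds.
    """
    if params is None:
        raise ValueError("params is required")
    if params.G != topo.degree + 1:
        raise ValueError(
            f"params.G = {params.G} but topology implies G = {topo.degree + 1}"
        )
    if initial.n_players != topo.n_players:
        raise ValueError("state size does not match topology")
    if engine not in ("numba", "python"):
        raise ValueError(f"unknown engine {engine!r}")

    t0 = initial.t
    counts0 = initial.counts()
    first_zero = np.full(4, -1, dtype=np.int64)
    first_zero[counts0 == 0] = t0

    if cfg.t_max == 0:
        return Trajectory(
            times=np.array([t0]),
            counts=counts0[None, :].astype(np.int64),
            n_players=initial.n_players,
            extinctions=_extinctions(first_zero),
            stop_reason="t_max",
            params=params,
            seed=cfg.seed,
        )

    out_counts = np.empty((cfg.t_max, 4), dtype=np.int64)

    if engine == "numba":
        if cfg.seed is None:
            kseed = int(initial.rng.integers(2**31))
        else:
            kseed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)
        _kernel.seed_rng(kseed)
        counts = counts0.astype(np.int64)
        n_done = int(
            _kernel.run_iterations(
                initial.strategies, topo.neighbors, counts, cfg.t_max, t0,
                params.r, params.beta, params.gamma, params.K, params.mu,
                out_counts, first_zero, cfg.stop_on_absorbing,
            )
        )
    else:
        n_done = _run_python(
            initial, topo, gmap, params, cfg, t0, out_counts, first_zero
        )

    initial.t = t0 + n_done
    idx = _record_indices(n_done, cfg.record_every)
    times = np.concatenate(([t0], t0 + idx + 1))
    counts_out = np.vstack([counts0.astype(np.int64), out_counts[idx]])
    stop_reason = "absorbing" if n_done < cfg.t_max else "t_max"
    return Trajectory(
        times=times,
        counts=counts_out,
        n_players=initial.n_players,
        extinctions=_extinctions(first_zero),
        stop_reason=stop_reason,
        params=params,
        seed=cfg.seed,
    )


def _run_python(
    state: SimulationState,
    topo: Topology,
    gmap: Optional[GroupMap],
    params: ModelParams,
    cfg: RunConfig,
    t0: int,
    out_counts: np.ndarray,
    first_zero: np.ndarray,
) -> int:
    counts = state.counts().astype(np.int64)
    n = state.n_players
    for it in range(cfg.t_max):
        t_now = t0 + it + 1
        for _ in range(n):
            ev = elementary_update(state, topo, gmap, params)
            if ev.changed:
                counts[ev.old] -= 1
                counts[ev.new] += 1
                if counts[ev.old] == 0 and first_zero[ev.old] < 0:
                    first_zero[ev.old] = t_now
        out_counts[it] = counts
        if cfg.stop_on_absorbing and int(np.count_nonzero(counts)) == 1:
            return it + 1
    return cfg.t_max


def _extinctions(first_zero: np.ndarray) -> dict[Strategy, Optional[int]]:
    return {
        Strategy(s): (int(first_zero[s]) if first_zero[s] >= 0 else None)
        for s in range(4)
    }


def simulate(
    params: ModelParams,
    L: int,
    t_max: int,
    seed: int,
    spec: str = "vonNeumann",
    balanced: bool = False,
    record_every: int = 1,
    stop_on_absorbing: bool = True,
    engine: str = "numba",
    topo: Optional[Topology] = None,
) -> Tuple[SimulationState, Trajectory]:
    """Build a lattice (unless given), initialize uniformly and run.

    A single user seed deterministically derives the initialization seed
    and the update-stream seed via ``SeedSequence``.  Returns the final
    state together with the trajectory.
    """
    if topo is None:
        topo = build_lattice(L, spec)
    init_seed, run_seed = (
        int(s) for s in np.random.SeedSequence(seed).generate_state(2)
    )
    state = initialize_uniform(topo, init_seed, balanced=balanced)
    cfg = RunConfig(
        t_max=t_max,
        record_every=record_every,
        stop_on_absorbing=stop_on_absorbing,
        seed=run_seed,
    )
    traj = run(state, cfg, topo, None, params, engine=engine)
    return state, traj
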