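"""Interaction structure: periodic lattices, overlapping groups, rewired graphs.

The default arena is an ``L x L`` square lattice with periodic boundary
conditions where every player has 4 nearest neighbors and belongs to five
overlapping groups of size ``G = 5``: the group it centers plus the groups
centered on each of its neighbors.  Larger neighborhoods (Moore ``G = 9``
up to a full 5x5 block, ``G = 25``) are provided as variants, as are
degree-preserving randomly rewired graphs that interpolate between the
lattice (``Q = 0``), small-world structures (small ``Q``) and random
4-regular graphs (``Q = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, Tuple, Union

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "NeighborhoodSpec",
    "Topology",
    "GroupMap",
    "neighborhood",
    "build_lattice",
    "build_group_map",
    "rewire",
    "is_connected",
    "NEIGHBORHOOD_NAMES",
]

Offset = Tuple[int, int]

# First ring in documented N, E, S, W order; (di, dj) with i the row index.
_FIRST_RING: Tuple[Offset, ...] = ((-1, 0), (0, 1), (1, 0), (0, -1))


def _ordered(offsets: Sequence[Offset]) -> Tuple[Offset, ...]:
    """First ring N,E,S,W, then remaining offsets by (Chebyshev radius, di, dj)."""
    rest = sorted(
        (o for o in offsets if o not in _FIRST_RING),
        key=lambda o: (max(abs(o[0]), abs(o[1])), o[0], o[1]),
    )
    first = [o for o in _FIRST_RING if o in offsets]
    return tuple(first) + tuple(rest)


def _block(radius: int) -> list[Offset]:
    return [
        (di, dj)
        for di in range(-radius, radius + 1)
        for dj in range(-radius, radius + 1)
        if (di, dj) != (0, 0)
    ]


_OFFSETS: dict[str, Tuple[Offset, ...]] = {
    # focal + 4 nearest neighbors: the default G=5 group structure
    "vonNeumann": _ordered(list(_FIRST_RING)),
    # 8 surrounding sites, G=9
    "moore": _ordered(_block(1)),
    # Manhattan distance <= 2 diamond, G=13
    "extended13": _ordered(
        [(di, dj) for di, dj in _block(2) if abs(di) + abs(dj) <= 2]
    ),
    # 5x5 block minus the 4 corners, G=21
    "extended21": _ordered(
        [(di, dj) for di, dj in _block(2) if abs(di) + abs(dj) < 4]
    ),
    # full 5x5 block, G=25
    "moore5x5": _ordered(_block(2)),
}

NEIGHBORHOOD_NAMES = tuple(_OFFSETS)


@dataclass(frozen=True)
class NeighborhoodSpec:
    """A named set of lattice displacements defining the interaction partners."""

    name: str
    offsets: Tuple[Offset, ...]

    def __post_init__(self) -> None:
        if (0, 0) in self.offsets:
            raise ValueError("offsets must exclude (0, 0)")
        if len(set(self.offsets)) != len(self.offsets):
            raise ValueError("duplicate offsets")
        negs = {(-di, -dj) for di, dj in self.offsets}
        if negs != set(self.offsets):
            raise ValueError("offsets must be symmetric under negation")

    @property
    def G(self) -> int:
        """Group size implied by this neighborhood: focal + partners."""
        return len(self.offsets) + 1

    @property
    def extent(self) -> int:
        return max(max(abs(di), abs(dj)) for di, dj in self.offsets)


def neighborhood(name: str) -> NeighborhoodSpec:
    """Look up a named neighborhood (vonNeumann, moore, extended13/21, moore5x5)."""
    try:
        return NeighborhoodSpec(name, _OFFSETS[name])
    except KeyError:
        raise ValueError(
            f"unknown neighborhood {name!r}; choose from {NEIGHBORHOOD_NAMES}"
        ) from None


@dataclass
class Topology:
    """Who interacts with whom.

    ``neighbors`` is an ``(n_players, degree)`` integer array; row ``x``
    lists the players adjacent to ``x``.  Adjacency is symmetric, without
    self-loops or duplicate edges, and every player has the same degree.
    """

    n_players: int
    neighbors: np.ndarray
    kind: str = "lattice"
    L: int | None = None
    spec_name: str | None = None

    def __post_init__(self) -> None:
        self.neighbors = np.ascontiguousarray(self.neighbors, dtype=np.int32)
        if self.neighbors.shape[0] != self.n_players:
            raise ValueError("neighbor table does not match n_players")

    @property
    def degree(self) -> int:
        return self.neighbors.shape[1]

    def edges(self) -> Iterator[Tuple[int, int]]:
        """Undirected edges as sorted (u, v) pairs, each exactly once."""
        for u in range(self.n_players):
            for v in self.neighbors[u]:
                if u < v:
                    yield (u, int(v))

    def edge_set(self) -> set[Tuple[int, int]]:
        return set(self.edges())

    def validate(self) -> None:
        """Check symmetry, no self-loops, no duplicate edges."""
        for u in range(self.n_players):
            row = self.neighbors[u]
            if len(set(row.tolist())) != len(row):
                raise ValueError(f"duplicate neighbor at player {u}")
            if u in row:
                raise ValueError(f"self-loop at player {u}")
            for v in row:
                if u not in self.neighbors[v]:
                    raise ValueError(f"asymmetric adjacency between {u} and {v}")

    def adjacency(self) -> coo_matrix:
        n, k = self.n_players, self.degree
        rows = np.repeat(np.arange(n), k)
        cols = self.neighbors.ravel()
        return coo_matrix((np.ones(n * k, dtype=np.int8), (rows, cols)), shape=(n, n))

    # -- plain-text serialization -------------------------------------------

    def to_edgelist(self, path: Union[str, Path]) -> None:
        """Write the edge set as two 0-based indices per line."""
        with open(path, "w") as fh:
            for u, v in self.edges():
                fh.write(f"{u} {v}\n")

    @classmethod
    def from_edgelist(
        cls, path: Union[str, Path], n_players: int, kind: str = "rewired"
    ) -> "Topology":
        adj: list[list[int]] = [[] for _ in range(n_players)]
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                u, v = map(int, line.split())
                adj[u].append(v)
                adj[v].append(u)
        degs = {len(a) for a in adj}
        if len(degs) != 1:
            raise ValueError(f"edge list is not regular: degrees {sorted(degs)}")
        return cls(n_players, np.array(adj, dtype=np.int32), kind=kind)


@dataclass
class GroupMap:
    """The overlapping groups: one per player, centered on it.

    A group consists of its center plus the center's neighbors (size
    ``G = degree + 1``); consequently every player belongs to exactly
    ``1 + degree`` groups (five in the default model).
    """

    topo: Topology
    G: int = field(init=False)

    def __post_init__(self) -> None:
        self.G = self.topo.degree + 1

    @property
    def n_groups(self) -> int:
        return self.topo.n_players

    def members(self, center: int) -> list[int]:
        """Members of the group centered at ``center`` (center first)."""
        return [center, *(int(v) for v in self.topo.neighbors[center])]

    def groups_of(self, player: int) -> list[int]:
        """Centers of the groups ``player`` belongs to (own group first)."""
        return [player, *(int(v) for v in self.topo.neighbors[player])]


def build_group_map(topo: Topology) -> GroupMap:
    """Construct the group map of a topology (one group per player)."""
    return GroupMap(topo)


def build_lattice(
    L: int, spec: Union[str, NeighborhoodSpec] = "vonNeumann"
) -> Topology:
    """Periodic ``L x L`` square lattice with the given neighborhood.

    Players are indexed row-major: site ``(i, j)`` is player ``i*L + j``,
    0-based, with torus wrap-around.  Neighbor lists follow the
    neighborhood's documented offset order (N, E, S, W first ring).
    """
    if isinstance(spec, str):
        spec = neighborhood(spec)
    min_L = 2 * spec.extent + 1
    if L < min_L:
        raise ValueError(
            f"L = {L} too small for neighborhood {spec.name!r}; need L >= {min_L}"
        )
    n = L * L
    i, j = np.divmod(np.arange(n), L)
    cols = []
    for di, dj in spec.offsets:
        cols.append(((i + di) % L) * L + ((j + dj) % L))
    neighbors = np.stack(cols, axis=1).astype(np.int32)
    return Topology(n, neighbors, kind="lattice", L=L, spec_name=spec.name)


def rewire(topo: Topology, Q: float, seed: int | None = None) -> Topology:
    """Degree-preserving random rewiring of a lattice.

    Each undirected link is independently marked for rewiring with
    probability ``Q``; marked links are then randomly paired and their
    endpoints exchanged (``(a,b),(c,d) -> (a,d),(c,b)``), which preserves
    every node's degree exactly.  Swaps that would create a self-loop or a
    duplicate edge are retried against other marked links a bounded number
    of times, then skipped.  ``Q = 0`` returns the lattice unchanged;
    ``Q = 1`` approximates a random regular graph with the same degree.
    """
    if not 0.0 <= Q <= 1.0:
        raise ValueError(f"rewiring fraction Q must be in [0, 1], got {Q}")
    if Q == 0.0:
        return Topology(
            topo.n_players, topo.neighbors.copy(), kind=topo.kind,
            L=topo.L, spec_name=topo.spec_name,
        )
    rng = np.random.default_rng(seed)
    edges = sorted(topo.edges())
    edge_set = set(edges)
    marked = [e for e in edges if rng.random() < Q]
    pool = list(marked)
    rng.shuffle(pool)

    max_retries = 8
    while len(pool) >= 2:
        a, b = pool.pop()
        done = False
        for _ in range(min(max_retries, len(pool))):
            idx = int(rng.integers(len(pool)))
            c, d = pool[idx]
            # two possible reconnections of the four endpoints
            for (p, q), (s, t) in (((a, d), (c, b)), ((a, c), (b, d))):
                e1 = (min(p, q), max(p, q))
                e2 = (min(s, t), max(s, t))
                if p == q or s == t or e1 == e2:
                    continue
                if e1 in edge_set or e2 in edge_set:
                    continue
                edge_set.discard((a, b))
                edge_set.discard((c, d))
                edge_set.add(e1)
                edge_set.add(e2)
                pool.pop(idx)
                done = True
                break
            if done:
                break
        # no valid partner found: leave edge (a, b) in place

    adj: list[list[int]] = [[] for _ in range(topo.n_players)]
    for u, v in sorted(edge_set):
        adj[u].append(v)
        adj[v].append(u)
    neighbors = np.array(adj, dtype=np.int32)
    return Topology(topo.n_players, neighbors, kind="rewired",
                    L=topo.L, spec_name=topo.spec_name)


def is_connected(topo: Topology) -> bool:
    """Whether the interaction graph is a single connected component."""
    n_comp, _ = connected_components(topo.adjacency(), directed=False)
    return n_comp == 1
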