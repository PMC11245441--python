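"""Synthetic structural networks and correlated sample-feature data.

The generator builds a signed, undirected structural network by a branching
process (a rooted tree grown node by node, plus a handful of random
cycle-forming edges), then synthesizes sample vectors whose pairwise Pearson
correlations follow the network: each node's value is drawn from a normal
distribution centred on the polarity-signed mean of its already-assigned
neighbours. Stacking ``m`` independent draws gives a sample-by-feature matrix
whose correlation structure encodes the network — the ground truth against
which clustering, bridge detection and network reconstruction are scored.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SynthConfig",
    "StructuralNetwork",
    "grow_structural_network",
    "assign_edge_polarities",
    "synthesize_sample",
    "synthesize_feature_matrix",
    "grow_barbell_network",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic-data generator.

    Parameters
    ----------
    phi : float
        Branching parameter in (0, 1]: the probability that the node
        currently being processed receives another child. High ``phi``
        produces hub-dominated networks; low ``phi`` produces chains.
    n : int
        Number of nodes (features). Default 500.
    m : int
        Number of synthesis replicates (samples). Default 400.
    sigma : float
        Standard deviation of the normal distribution used for every value
        draw. Default 0.2.
    n_extra_edges : int
        Number of random cycle-forming edges added after the tree phase.
        Default 10.
    seed : int or None
        Seed for the generator's own RNG when no external one is supplied.
    """

    phi: float = 0.8
    n: int = 500
    m: int = 400
    sigma: float = 0.2
    n_extra_edges: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.phi <= 1.0):
            raise ValueError(f"phi must be in (0, 1], got {self.phi}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        max_extra = self.n * (self.n - 1) // 2 - (self.n - 1)
        if not (0 <= self.n_extra_edges <= max_extra):
            raise ValueError(
                f"n_extra_edges must be in [0, {max_extra}] for n={self.n}, "
                f"got {self.n_extra_edges}"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self, path) -> None:
        import dataclasses
        import json

        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SynthConfig":
        import json

        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass(frozen=True)
class StructuralNetwork:
    """A signed, undirected, connected graph on nodes ``0..n-1``.

    ``edges`` is an (E, 2) int array with each row ``(a, b)``, ``a < b``;
    ``polarities`` is an (E,) array of +1/-1, or None before polarity
    assignment.
    """

    n: int
    edges: np.ndarray
    polarities: np.ndarray | None = None
    _adjacency: list | None = field(
        default=None, repr=False, compare=False, hash=False
    )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-node ``(neighbor_ids, polarities)`` arrays, neighbours ascending.

        Requires polarities. Cached after first call.
        """
        if self._adjacency is not None:
            return self._adjacency
        if self.polarities is None:
            raise ValueError("polarities not assigned yet")
        nbrs: list[list[tuple[int, int]]] = [[] for _ in range(self.n)]
        for (a, b), eps in zip(self.edges, self.polarities):
            nbrs[a].append((b, eps))
            nbrs[b].append((a, eps))
        adj = []
        for lst in nbrs:
            lst.sort()
            ids = np.array([x for x, _ in lst], dtype=np.intp)
            eps = np.array([e for _, e in lst], dtype=np.float64)
            adj.append((ids, eps))
        object.__setattr__(self, "_adjacency", adj)
        return adj

    def neighbor_sets(self) -> list[set[int]]:
        """Plain neighbour sets (no polarity needed)."""
        out: list[set[int]] = [set() for _ in range(self.n)]
        for a, b in self.edges:
            out[a].add(int(b))
            out[b].add(int(a))
        return out

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        if self.polarities is None:
            g.add_edges_from(map(tuple, self.edges))
        else:
            g.add_edges_from(
                (int(a), int(b), {"polarity": int(e)})
                for (a, b), e in zip(self.edges, self.polarities)
            )
        return g


def _canonical_edges(pairs: list[tuple[int, int]]) -> np.ndarray:
    arr = np.array([(min(a, b), max(a, b)) for a, b in pairs], dtype=np.intp)
    if arr.size == 0:
        arr = arr.reshape(0, 2)
    return arr


def grow_structural_network(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> StructuralNetwork:
    """Grow a connected network: branching-process tree plus random cycles.

    The tree phase processes nodes in FIFO order of creation. For the
    current node, uniform draws on [0, 1) are taken repeatedly; each draw
    below ``phi`` adds a new child, and the first draw at or above ``phi``
    moves on to the next node. Growth halts the instant the node count
    reaches ``n``, even mid-batch. Should the queue empty before ``n``
    nodes exist, a uniformly chosen existing node is re-enqueued so the
    process always terminates. Finally ``n_extra_edges`` edges are added
    between uniformly chosen non-adjacent pairs.

    Returns a network without polarities; see :func:`assign_edge_polarities`.
    """
    if rng is None:
        rng = config.rng()
    n = config.n
    edges: list[tuple[int, int]] = []
    n_nodes = 1
    queue: deque[int] = deque([0])
    while n_nodes < n:
        if not queue:
            queue.append(int(rng.integers(n_nodes)))
        current = queue.popleft()
        while n_nodes < n and rng.uniform() < config.phi:
            child = n_nodes
            n_nodes += 1
            edges.append((current, child))
            queue.append(child)

    adjacent = set(map(frozenset, edges))
    added = 0
    while added < config.n_extra_edges:
        a, b = rng.integers(n, size=2)
        if a == b:
            continue
        key = frozenset((int(a), int(b)))
        if key in adjacent:
            continue
        adjacent.add(key)
        edges.append((int(a), int(b)))
        added += 1

    return StructuralNetwork(n=n, edges=_canonical_edges(edges))


def assign_edge_polarities(
    net: StructuralNetwork, rng: np.random.Generator
) -> StructuralNetwork:
    """Label a uniformly random half of the edges +1, the rest -1.

    With an odd edge count, ``floor(E/2)`` edges are positive.
    """
    if net.polarities is not None:
        raise ValueError("polarities already assigned")
    n_edges = net.n_edges
    polarities = np.full(n_edges, -1, dtype=np.int8)
    if n_edges:
        positive = rng.choice(n_edges, size=n_edges // 2, replace=False)
        polarities[positive] = 1
    return replace(net, polarities=polarities)


def synthesize_sample(
    net: StructuralNetwork, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Assign one value per node by signed-mean propagation from a random seed.

    A seed node is chosen uniformly and drawn from N(0, sigma). Remaining
    nodes are visited breadth-first from the seed (children in ascending id
    order); each is drawn from N(mu, sigma) where mu is the mean of
    polarity-signed values over its already-assigned neighbours, or 0 if it
    has none.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    adj = net.adjacency()
    n = net.n
    values = np.zeros(n)
    assigned = np.zeros(n, dtype=bool)

    seed = int(rng.integers(n))
    values[seed] = rng.normal(0.0, sigma)
    assigned[seed] = True

    queue: deque[int] = deque([seed])
    queued = np.zeros(n, dtype=bool)
    queued[seed] = True
    while queue:
        node = queue.popleft()
        if not assigned[node]:
            ids, eps = adj[node]
            mask = assigned[ids]
            k = int(mask.sum())
            mu = float(eps[mask] @ values[ids[mask]]) / k if k else 0.0
            values[node] = rng.normal(mu, sigma)
            assigned[node] = True
        for nb in adj[node][0]:
            if not queued[nb]:
                queued[nb] = True
                queue.append(int(nb))
    if not assigned.all():
        raise ValueError("structural network is not connected")
    return values


def synthesize_feature_matrix(
    net: StructuralNetwork,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Stack ``m`` independent synthesis replicates into an (m, n) matrix."""
    if rng is None:
        rng = config.rng()
    return np.vstack(
        [synthesize_sample(net, config.sigma, rng) for _ in range(config.m)]
    )


def grow_barbell_network(
    n_side: int,
    phi: float,
    rng: np.random.Generator,
) -> tuple[StructuralNetwork, int]:
    """Two branched-tree communities joined by a single cut node.

    Grows two independent trees of ``n_side`` nodes with branching
    parameter ``phi``, then joins their roots through one extra node — the
    planted bridge. Returns the polarized network and the cut node's id
    (``2 * n_side``). Used as a benchmark where the ground-truth bridge set
    is known exactly.
    """
    cfg = SynthConfig(phi=phi, n=n_side, m=2, sigma=0.2, n_extra_edges=0)
    left = grow_structural_network(cfg, rng)
    right = grow_structural_network(cfg, rng)
    cut = 2 * n_side
    edges = [tuple(e) for e in left.edges]
    edges += [(int(a) + n_side, int(b) + n_side) for a, b in right.edges]
    edges += [(0, cut), (n_side, cut)]
    net = StructuralNetwork(n=cut + 1, edges=_canonical_edges(edges))
    return assign_edge_polarities(net, rng), cut
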