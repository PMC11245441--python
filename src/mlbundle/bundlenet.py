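"""Bundle-network reconstruction and evaluation.

Two bundle-level score matrices summarize how bundles relate: the bundle
affinity matrix H (mean cross-bundle affinity) and the bundle co-cluster
matrix L (accumulated fraction of shared clusters across the regime
horizon — the "history" of co-clustering that plain spectral clustering
discards). Either matrix, or their normalized sum, is converted to a graph
over bundles by a two-step rule: every row contributes an edge to its
largest off-diagonal entry, then remaining entries are scanned in
descending order and added only when they merge connected components.
Against synthetic data the reconstruction is scored by the Jaccard index
of its edge set with the target network obtained by projecting bundles
onto the generating structural network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bridges import project_group_adjacency
from .bundling import BundleLayer
from .spectral import AffinityPair, ClusteringRegime
from .synth import StructuralNetwork

__all__ = [
    "BundleNetwork",
    "bundle_affinity_matrix",
    "bundle_cocluster_matrix",
    "combine_scores",
    "score_matrix_to_network",
    "target_bundle_network",
    "jaccard_index",
    "classify_edges",
]

Edge = tuple[int, int]


@dataclass(frozen=True)
class BundleNetwork:
    """Undirected graph over the bundle ids of one layer.

    ``edges`` hold unordered pairs stored as ``(a, b)`` with ``a < b``.
    ``method`` tags the construction: "H", "L", "LH" or "target".
    """

    n_nodes: int
    edges: frozenset[Edge]
    method: str

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph(method=self.method)
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


def bundle_affinity_matrix(
    ap: AffinityPair, layer: BundleLayer
) -> np.ndarray:
    """Mean cross-bundle affinity: H[x, y] = mean of A over beta_x × beta_y.

    The diagonal follows the same formula (the affinity's zero diagonal
    contributes zeros) but is never used for edge selection.
    """
    A = ap.affinity
    if A.shape[0] != len(layer.labels):
        raise ValueError("affinity and bundle layer cover different features")
    N = layer.n_bundles
    indicator = np.zeros((A.shape[0], N))
    indicator[np.arange(A.shape[0]), layer.labels] = 1.0
    sums = indicator.T @ A @ indicator
    sizes = layer.sizes().astype(np.float64)
    return sums / np.outer(sizes, sizes)


def bundle_cocluster_matrix(
    regimes: list[ClusteringRegime],
    layer: BundleLayer,
    k: int | None = None,
    r: int | None = None,
) -> np.ndarray:
    """Bundle co-cluster matrix L at layer k over regime horizon r.

    For regimes up to k — which the layer refines, so each bundle sits in
    exactly one cluster — two bundles sharing cluster xi contribute
    ``(|beta_x| + |beta_y|) / |xi|``. For regimes k+1..r, every cluster xi
    holding members of both bundles contributes
    ``(|beta_x ∩ xi| + |beta_y ∩ xi|) / |xi|``. The diagonal is 0.
    """
    k = layer.layer if k is None else k
    r = len(regimes) if r is None else r
    if k != layer.layer:
        raise ValueError(f"layer is {layer.layer} but k={k}")
    if not k <= r <= len(regimes):
        raise ValueError(f"need k <= r <= {len(regimes)}, got k={k}, r={r}")
    N = layer.n_bundles
    sizes = layer.sizes().astype(np.float64)
    L = np.zeros((N, N))

    for regime in regimes[:k]:
        counts = _crosstab(layer.labels, regime.labels, N)
        cluster_sizes = counts.sum(axis=0)
        # refinement: each bundle occupies exactly one cluster per regime <= k
        home = counts.argmax(axis=1)
        same = home[:, None] == home[None, :]
        L += same * (sizes[:, None] + sizes[None, :]) / cluster_sizes[home][:, None]

    for regime in regimes[k:r]:
        counts = _crosstab(layer.labels, regime.labels, N)
        cluster_sizes = counts.sum(axis=0)
        frac = counts / cluster_sizes
        present = (counts > 0).astype(np.float64)
        L += frac @ present.T + present @ frac.T

    np.fill_diagonal(L, 0.0)
    return (L + L.T) / 2.0


def _crosstab(bundle_labels, cluster_labels, n_bundles) -> np.ndarray:
    """(n_bundles, n_clusters) membership counts with dense cluster ids."""
    _, dense = np.unique(cluster_labels, return_inverse=True)
    n_clusters = dense.max() + 1
    counts = np.zeros((n_bundles, n_clusters))
    np.add.at(counts, (np.asarray(bundle_labels), dense), 1.0)
    return counts


def combine_scores(H: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Min-max scale each matrix over its off-diagonal entries, then add.

    A constant off-diagonal matrix scales to zeros. Output is symmetric
    with zero diagonal.
    """
    if H.shape != L.shape:
        raise ValueError("score matrices have mismatched shapes")
    return _minmax_offdiag(H) + _minmax_offdiag(L)


def _minmax_offdiag(M: np.ndarray) -> np.ndarray:
    N = M.shape[0]
    out = np.zeros_like(M, dtype=np.float64)
    if N < 2:
        return out
    mask = ~np.eye(N, dtype=bool)
    vals = M[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        out[mask] = (M[mask] - lo) / (hi - lo)
    return out


def score_matrix_to_network(
    M: np.ndarray, method: str = "H"
) -> BundleNetwork:
    """Two-step edge selection from a symmetric bundle-score matrix.

    Step 1: each row adds an edge to its maximal off-diagonal entry (ties
    to the smallest column index); duplicates collapse, leaving at most
    N - 1 distinct edges. Step 2: while more than one connected component
    remains, unused off-diagonal entries are scanned once in descending
    order (ties lexicographic by (row, col)) and an edge is added exactly
    when it reduces the component count.
    """
    M = np.asarray(M, dtype=np.float64)
    N = M.shape[0]
    if N == 0:
        raise ValueError("empty score matrix")
    edges: set[Edge] = set()
    if N >= 2:
        masked = M.copy()
        np.fill_diagonal(masked, -np.inf)
        for i in range(N):
            j = int(np.argmax(masked[i]))  # argmax returns the first maximum
            edges.add((min(i, j), max(i, j)))

    parent = list(range(N))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n_components = N
    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            n_components -= 1

    if n_components > 1:
        iu, ju = np.triu_indices(N, k=1)
        order = np.lexsort((ju, iu, -M[iu, ju]))
        for idx in order:
            a, b = int(iu[idx]), int(ju[idx])
            if (a, b) in edges:
                continue
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
                edges.add((a, b))
                n_components -= 1
                if n_components == 1:
                    break

    return BundleNetwork(n_nodes=N, edges=frozenset(edges), method=method)


def target_bundle_network(
    layer: BundleLayer, structural_net: StructuralNetwork
) -> BundleNetwork:
    """Ground-truth bundle graph: bundles joined by any structural edge."""
    adjacency = project_group_adjacency(layer, structural_net)
    edges = frozenset(
        (min(x, y), max(x, y))
        for x, nbrs in adjacency.items()
        for y in nbrs
        if x < y
    )
    return BundleNetwork(
        n_nodes=layer.n_bundles, edges=edges, method="target"
    )


def jaccard_index(net_r: BundleNetwork, net_t: BundleNetwork) -> float:
    """|E_r ∩ E_t| / |E_r ∪ E_t|; defined as 1.0 when both are empty."""
    union = net_r.edges | net_t.edges
    if not union:
        return 1.0
    return len(net_r.edges & net_t.edges) / len(union)


def classify_edges(
    net_r: BundleNetwork, net_t: BundleNetwork
) -> tuple[frozenset[Edge], frozenset[Edge], frozenset[Edge]]:
    """(true positives, false negatives, false positives) edge sets.

    True positives are edges in both networks; false negatives are target
    edges the reconstruction missed; false positives are reconstructed
    edges absent from the target.
    """
    tp = net_r.edges & net_t.edges
    fn = net_t.edges - net_r.edges
    fp = net_r.edges - net_t.edges
    return frozenset(tp), frozenset(fn), frozenset(fp)
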