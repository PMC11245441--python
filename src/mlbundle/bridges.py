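"""Bridge-factor computation for clusters or bundles.

A bridge set is a small group of features joining two or more much larger
groups. For group ``x`` with neighbour set ``N_x`` on a group-level
adjacency, the bridge factor is the product of neighbour-to-self size
ratios, ``gamma_x = prod_{y in N_x} |y| / |x|`` when ``|N_x| > 1`` and 0
otherwise — large exactly when a small group couples several big ones.
The neighbour graph is pluggable: projection of a known structural network
(synthetic validation) or a reconstructed bundle network (real data).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import StructuralNetwork

__all__ = ["project_group_adjacency", "bridge_factors"]


def _group_labels(partition) -> np.ndarray:
    """Accept a label array, ClusteringRegime or BundleLayer."""
    labels = getattr(partition, "labels", partition)
    return np.asarray(labels, dtype=np.intp)


def project_group_adjacency(
    partition, structural_net: StructuralNetwork
) -> dict[int, set[int]]:
    """Neighbour sets of groups projected onto a structural network.

    Groups x and y are adjacent iff some structural edge joins a member of
    x to a member of y. Self-adjacency is excluded. Every group present in
    the partition gets an entry (possibly empty).
    """
    labels = _group_labels(partition)
    if len(labels) != structural_net.n:
        raise ValueError(
            f"partition covers {len(labels)} nodes but network has "
            f"{structural_net.n}"
        )
    adjacency: dict[int, set[int]] = {int(g): set() for g in np.unique(labels)}
    for a, b in structural_net.edges:
        ga, gb = int(labels[a]), int(labels[b])
        if ga != gb:
            adjacency[ga].add(gb)
            adjacency[gb].add(ga)
    return adjacency


def bridge_factors(
    partition, adjacency: dict[int, set[int]]
) -> pd.DataFrame:
    """Bridge factor of every group against a group-level adjacency.

    Returns a frame with columns ``group_id, size, n_neighbors, gamma,
    log10_gamma``, sorted by group id. The product is accumulated in log
    space so that many large size ratios cannot overflow; ``gamma`` is the
    exponentiated value (possibly ``inf`` for extreme products) and
    ``log10_gamma`` is NaN where gamma is 0.
    """
    labels = _group_labels(partition)
    sizes = {int(g): int(c) for g, c in zip(*np.unique(labels, return_counts=True))}
    if set(adjacency) - set(sizes):
        raise ValueError("adjacency refers to groups absent from the partition")
    rows = []
    for g in sorted(sizes):
        size = sizes[g]
        if size == 0:
            raise ValueError(f"group {g} is empty")
        neighbors = adjacency.get(g, set())
        if len(neighbors) > 1:
            log10_gamma = float(
                sum(np.log10(sizes[y] / size) for y in neighbors)
            )
            gamma = float(10.0 ** log10_gamma)
        else:
            gamma, log10_gamma = 0.0, float("nan")
        rows.append(
            {
                "group_id": g,
                "size": size,
                "n_neighbors": len(neighbors),
                "gamma": gamma,
                "log10_gamma": log10_gamma,
            }
        )
    return pd.DataFrame(rows)


def max_gamma_group(report: pd.DataFrame) -> int:
    """Group id attaining the largest bridge factor (ties: smaller id).

    Uses ``log10_gamma`` where finite so that products beyond float range
    still compare correctly.
    """
    key = report["log10_gamma"].fillna(-np.inf).to_numpy()
    best = int(np.argmax(key))
    return int(report["group_id"].iloc[best])
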