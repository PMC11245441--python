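"""Plain-TSV readers and writers for every pipeline artifact.

All tables are tab-separated with ``#``-prefixed metadata header lines
(version, seed, parameters) so outputs are greppable and diffable. Node,
feature and bundle ids are 0-based throughout; feature columns are named
``f0..f{n-1}``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synth import StructuralNetwork

__version__ = "0.1.0"


def _header_lines(meta: dict | None) -> str:
    lines = [f"# mlbundle {__version__}"]
    for key, val in (meta or {}).items():
        lines.append(f"# {key}={val}")
    return "\n".join(lines) + "\n"


def _write_frame(frame: pd.DataFrame, path, meta: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        frame.to_csv(fh, sep="\t", index=False)


def _read_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- structural network edge lists ------------------------------------------

def write_edge_list(net: StructuralNetwork, path, meta: dict | None = None):
    pol = (
        net.polarities
        if net.polarities is not None
        else np.zeros(net.n_edges, dtype=int)
    )
    frame = pd.DataFrame(
        {
            "node_a": net.edges[:, 0],
            "node_b": net.edges[:, 1],
            "polarity": pol,
        }
    )
    meta = {"n_nodes": net.n, **(meta or {})}
    _write_frame(frame, path, meta)


def read_edge_list(path) -> StructuralNetwork:
    n_nodes = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# n_nodes="):
                n_nodes = int(line.split("=", 1)[1])
            if not line.startswith("#"):
                break
    frame = _read_frame(path)
    edges = frame[["node_a", "node_b"]].to_numpy(dtype=np.intp)
    if n_nodes is None:
        n_nodes = int(edges.max()) + 1 if len(edges) else 0
    pol = frame["polarity"].to_numpy(dtype=np.int8)
    polarities = pol if np.abs(pol).all() else None
    return StructuralNetwork(n=n_nodes, edges=edges, polarities=polarities)


# -- feature matrices and affinities ----------------------------------------

def write_feature_matrix(S: np.ndarray, path, meta: dict | None = None):
    frame = pd.DataFrame(S, columns=[f"f{i}" for i in range(S.shape[1])])
    _write_frame(frame, path, meta)


def read_feature_matrix(path) -> np.ndarray:
    return _read_frame(path).to_numpy(dtype=np.float64)


def write_matrix(M: np.ndarray, path, prefix: str = "b", meta=None):
    """Square matrix with labelled header (bundle/feature ids)."""
    frame = pd.DataFrame(M, columns=[f"{prefix}{i}" for i in range(M.shape[1])])
    _write_frame(frame, path, meta)


def read_matrix(path) -> np.ndarray:
    return _read_frame(path).to_numpy(dtype=np.float64)


# -- labels, bundles, profiles, reports -------------------------------------

def write_eigen_table(spectrum, path, meta=None):
    lam = spectrum.eigenvalues
    gaps = spectrum.eigengaps
    rank = np.empty(len(gaps), dtype=int)
    rank[spectrum.regime_order - 1] = np.arange(1, len(gaps) + 1)
    frame = pd.DataFrame(
        {
            "index": np.arange(1, len(lam) + 1),
            "eigenvalue": lam,
            "eigengap": np.append(gaps, np.nan),
            "prominence_rank": np.append(rank, -1),
        }
    )
    _write_frame(frame, path, meta)


def write_regime_labels(regimes, path, meta=None):
    n = len(regimes[0].labels)
    frame = pd.DataFrame({"feature_id": np.arange(n)})
    for reg in regimes:
        frame[f"regime_{reg.rank}"] = reg.labels
    _write_frame(frame, path, meta)


def write_bundle_assignments(layers, path, meta=None):
    rows = []
    for bl in layers:
        for feat, lab in enumerate(bl.labels):
            rows.append((feat, bl.layer, int(lab)))
    frame = pd.DataFrame(rows, columns=["feature_id", "layer", "bundle_id"])
    _write_frame(frame, path, meta)


def read_bundle_assignments(path) -> pd.DataFrame:
    return _read_frame(path)


def write_size_profile(profile: pd.DataFrame, path, meta=None):
    meta = dict(meta or {})
    if profile.attrs.get("plateau") is not None:
        meta["plateau_layer"] = profile.attrs["plateau"]
    _write_frame(profile, path, meta)


def write_bridge_report(report: pd.DataFrame, path, meta=None):
    _write_frame(report, path, meta)


def write_network(net, path, meta=None):
    edges = sorted(net.edges)
    frame = pd.DataFrame(
        {
            "bundle_a": [a for a, _ in edges],
            "bundle_b": [b for _, b in edges],
            "method": net.method,
        }
    )
    meta = {"n_nodes": net.n_nodes, "method": net.method, **(meta or {})}
    _write_frame(frame, path, meta)


def read_network(path):
    from .bundlenet import BundleNetwork

    n_nodes, method = None, "?"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# n_nodes="):
                n_nodes = int(line.split("=", 1)[1])
            elif line.startswith("# method="):
                method = line.split("=", 1)[1].strip()
            if not line.startswith("#"):
                break
    frame = _read_frame(path)
    edges = frozenset(
        (int(a), int(b))
        for a, b in zip(frame["bundle_a"], frame["bundle_b"])
    )
    if n_nodes is None:
        n_nodes = max((max(e) for e in edges), default=-1) + 1
    return BundleNetwork(n_nodes=n_nodes, edges=edges, method=method)


def write_graphml(net, path):
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)


def write_sankey(layers, path, meta=None):
    """Member flow between consecutive layers, for external Sankey plots."""
    rows = []
    for prev, cur in zip(layers, layers[1:]):
        pairs, counts = np.unique(
            np.stack([prev.labels, cur.labels], axis=1), axis=0,
            return_counts=True,
        )
        for (b_from, b_to), c in zip(pairs, counts):
            rows.append(
                (prev.layer, int(b_from), cur.layer, int(b_to), int(c))
            )
    frame = pd.DataFrame(
        rows,
        columns=["layer_from", "bundle_from", "layer_to", "bundle_to",
                 "n_members"],
    )
    _write_frame(frame, path, meta)


def write_evaluation(rows: list[dict], path, meta=None):
    frame = pd.DataFrame(
        rows, columns=["method", "n_edges", "tp", "fn", "fp", "jaccard"]
    )
    _write_frame(frame, path, meta)
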