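"""Multi-layer bundling: recursive intersection of clustering regimes.

A *bundle* of layer ``l`` is a maximal set of features that share a cluster
in each of the ``l`` most prominent clustering regimes; equivalently, the
nonempty intersections of one cluster drawn from every regime 1..l. Layers
refine: once two features land in different bundles they never rejoin at a
deeper layer. The central entry point is :class:`MultiLayerBundling`, a
scikit-learn style estimator running the full pipeline (affinity ->
Laplacian spectrum -> eigengap-ranked regimes -> bundle layers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .spectral import (
    AffinityPair,
    ClusteringRegime,
    Spectrum,
    affinity_from_matrix,
    compute_affinity,
    eigendecompose_and_rank,
    normalized_laplacian,
    top_regimes,
)

__all__ = [
    "BundleLayer",
    "form_bundles",
    "bundle_size_profile",
    "bundle_eigengene",
    "MultiLayerBundling",
]


@dataclass(frozen=True)
class BundleLayer:
    """The partition of features into bundles at one layer.

    ``bundles[b]`` is the sorted member-id array of bundle ``b``; ids are
    canonical — descending size, ties to the smallest member id — so that
    bundle 0 is always a largest bundle. ``provenance[b]`` is the tuple of
    regime labels (regime 1, ..., regime ``layer``) that defines the bundle.
    """

    layer: int
    labels: np.ndarray
    bundles: tuple[np.ndarray, ...]
    provenance: tuple[tuple[int, ...], ...]

    @property
    def n_bundles(self) -> int:
        return len(self.bundles)

    def sizes(self) -> np.ndarray:
        return np.array([len(b) for b in self.bundles], dtype=np.intp)


def form_bundles(regimes: list[ClusteringRegime], layer: int) -> BundleLayer:
    """Intersect the first ``layer`` regimes into a bundle partition.

    Bundles are the equivalence classes of the per-feature label tuple
    (label in regime 1, ..., label in regime ``layer``) — identical to
    enumerating all nonempty cluster intersections, but linear in n.
    """
    if not 1 <= layer <= len(regimes):
        raise ValueError(f"layer must be in [1, {len(regimes)}]")
    used = regimes[:layer]
    n = len(used[0].labels)
    if any(len(r.labels) != n for r in used):
        raise ValueError("regimes cover mismatched feature sets")
    key = np.stack([r.labels for r in used], axis=1)
    _, inverse = np.unique(key, axis=0, return_inverse=True)

    groups: dict[int, list[int]] = {}
    for feat, g in enumerate(inverse):
        groups.setdefault(int(g), []).append(feat)
    members = [np.array(v, dtype=np.intp) for v in groups.values()]
    members.sort(key=lambda b: (-len(b), int(b[0])))

    labels = np.empty(n, dtype=np.intp)
    provenance = []
    for bid, b in enumerate(members):
        labels[b] = bid
        provenance.append(tuple(int(x) for x in key[b[0]]))
    return BundleLayer(
        layer=layer,
        labels=labels,
        bundles=tuple(members),
        provenance=tuple(provenance),
    )


def bundle_size_profile(
    layers: list[BundleLayer], thresholds: tuple[int, ...] = (1, 5, 50)
) -> pd.DataFrame:
    """Count bundles of at least each threshold size, per layer.

    The returned frame has columns ``layer, threshold, count`` plus, via
    the ``plateau`` attribute in ``frame.attrs``, the first layer at which
    every threshold count is unchanged from the previous layer (None if
    the counts never stabilize). The profile is the practical guide for
    choosing a stopping layer: deeper layers only refine, and once the
    size distribution stops moving, further layers add little.
    """
    rows = []
    counts_by_layer = []
    for bl in layers:
        sizes = bl.sizes()
        counts = tuple(int((sizes >= t).sum()) for t in thresholds)
        counts_by_layer.append(counts)
        for t, c in zip(thresholds, counts):
            rows.append({"layer": bl.layer, "threshold": t, "count": c})
    frame = pd.DataFrame(rows, columns=["layer", "threshold", "count"])
    plateau = None
    for prev, cur, bl in zip(counts_by_layer, counts_by_layer[1:], layers[1:]):
        if prev == cur:
            plateau = bl.layer
            break
    frame.attrs["plateau"] = plateau
    return frame


def bundle_eigengene(S: np.ndarray, bundle: np.ndarray) -> np.ndarray:
    """First principal-component score of a bundle's feature submatrix.

    Features are standardized (mean 0, unit variance) before the
    decomposition, and the sign is fixed so the eigengene correlates
    nonnegatively with the bundle's mean standardized feature — the module
    eigengene convention of co-expression analysis.
    """
    bundle = np.asarray(bundle, dtype=np.intp)
    if bundle.size == 0:
        raise ValueError("bundle is empty")
    sub = np.asarray(S, dtype=np.float64)[:, bundle]
    sd = sub.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = bundle[sd == 0]
        raise ValueError(f"zero-variance feature(s) in bundle: {bad.tolist()}")
    Z = (sub - sub.mean(axis=0)) / sd
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    score = U[:, 0] * s[0]
    if score @ Z.mean(axis=1) < 0:
        score = -score
    return score


class MultiLayerBundling(ClusterMixin, BaseEstimator):
    """Multi-resolution consensus clustering of correlated features.

    Fits the full pipeline on a sample-by-feature matrix: Pearson
    affinity ``A = |R|``, normalized Laplacian, eigengap-ranked clustering
    regimes, and ``n_layers`` bundle layers by recursive intersection.

    Parameters
    ----------
    n_layers : int, default=5
        Number of bundle layers to form (the parameter ``k``). Layer
        ``n_layers`` supplies ``labels_``.
    n_regimes : int, default=12
        Number of prominence-ranked clustering regimes to compute (the
        horizon ``r``); must be at least ``n_layers``. Regimes beyond
        ``n_layers`` feed the bundle co-cluster matrix.
    affinity : {"pearson", "precomputed"}, default="pearson"
        With "pearson", ``X`` is an (m, n) sample-by-feature matrix; with
        "precomputed", ``X`` is an (n, n) symmetric nonnegative affinity.

    Attributes
    ----------
    affinity_ : AffinityPair
        Correlation and affinity matrices.
    spectrum_ : Spectrum
        Laplacian eigenstructure, eigengaps and prominence order.
    regimes_ : list of ClusteringRegime
        The ``n_regimes`` most prominent regimes, rank ascending.
    layers_ : list of BundleLayer
        Bundle layers 1..``n_layers``.
    labels_ : ndarray of shape (n_features,)
        Bundle label of each feature at layer ``n_layers``.
    """

    def __init__(
        self,
        n_layers: int = 5,
        n_regimes: int = 12,
        affinity: str = "pearson",
    ):
        self.n_layers = n_layers
        self.n_regimes = n_regimes
        self.affinity = affinity

    def fit(self, X, y=None) -> "MultiLayerBundling":
        if self.affinity not in ("pearson", "precomputed"):
            raise ValueError(f"unknown affinity {self.affinity!r}")
        if not 1 <= self.n_layers <= self.n_regimes:
            raise ValueError("need 1 <= n_layers <= n_regimes")
        X = np.asarray(X, dtype=np.float64)
        if self.affinity == "pearson":
            ap: AffinityPair = compute_affinity(X)
        else:
            ap = affinity_from_matrix(X)
        n = ap.n_features
        if self.n_regimes > n - 1:
            raise ValueError(
                f"n_regimes={self.n_regimes} exceeds n_features-1={n - 1}"
            )
        spec: Spectrum = eigendecompose_and_rank(normalized_laplacian(ap))
        regimes = top_regimes(spec, self.n_regimes)
        layers = [
            form_bundles(regimes, layer)
            for layer in range(1, self.n_layers + 1)
        ]
        self.affinity_ = ap
        self.spectrum_ = spec
        self.regimes_ = regimes
        self.layers_ = layers
        self.labels_ = layers[-1].labels
        self.n_features_in_ = X.shape[1]
        return self

    def bundle_layer(self, layer: int) -> BundleLayer:
        """The fitted :class:`BundleLayer` at 1-based ``layer``."""
        self._check_fitted()
        if not 1 <= layer <= self.n_layers:
            raise ValueError(f"layer must be in [1, {self.n_layers}]")
        return self.layers_[layer - 1]

    def size_profile(
        self, thresholds: tuple[int, ...] = (1, 5, 50)
    ) -> pd.DataFrame:
        """Bundle-count-by-size table across fitted layers."""
        self._check_fitted()
        return bundle_size_profile(self.layers_, thresholds)

    def eigengenes(self, S: np.ndarray, layer: int | None = None) -> np.ndarray:
        """Per-bundle eigengenes at ``layer`` (default: deepest), (m, N)."""
        self._check_fitted()
        bl = self.layers_[(layer or self.n_layers) - 1]
        return np.column_stack(
            [bundle_eigengene(S, b) for b in bl.bundles]
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "layers_"):
            raise ValueError("estimator is not fitted yet; call fit first")
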