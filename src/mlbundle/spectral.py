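"""Affinity construction, normalized Laplacian, eigengap ranking, regimes.

Spectral clustering on a correlation network. The affinity is the
elementwise absolute Pearson correlation with a zeroed diagonal; its
normalized Laplacian ``Qhat = D^{-1/2} (D - A) D^{-1/2}`` is positive
semi-definite with smallest eigenvalue 0. Gaps between consecutive
ascending eigenvalues (eigengaps) flag natural cluster counts: the i-th
largest gap, at eigenvalue index kappa_i, defines the i-th most prominent
*clustering regime* — a partition into kappa_i clusters obtained by
QR-pivot label assignment (cluster-qr) on the first kappa_i eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

ZERO_TOL = 1e-8

__all__ = [
    "AffinityPair",
    "Spectrum",
    "ClusteringRegime",
    "compute_affinity",
    "normalized_laplacian",
    "eigendecompose_and_rank",
    "cluster_qr",
    "cluster_regime",
    "top_regimes",
]


@dataclass(frozen=True)
class AffinityPair:
    """Pearson correlation matrix R and affinity A = |R| with zero diagonal."""

    correlation: np.ndarray
    affinity: np.ndarray

    @property
    def n_features(self) -> int:
        return self.affinity.shape[0]


@dataclass
class Spectrum:
    """Laplacian eigenstructure and eigengap prominence ranking.

    ``eigenvalues`` ascend; ``eigengaps[i]`` is ``lam[i+1] - lam[i]``
    (0-based storage of the gap after the (i+1)-th eigenvalue), and
    ``regime_order`` lists cluster counts ``kappa_1, kappa_2, ...`` —
    eigenvalue indices sorted by descending gap, ties to the smaller index.
    """

    degree: np.ndarray
    laplacian: np.ndarray
    norm_laplacian: np.ndarray
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None
    eigengaps: np.ndarray | None = None
    regime_order: np.ndarray | None = None
    _regime_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_features(self) -> int:
        return self.norm_laplacian.shape[0]


@dataclass(frozen=True)
class ClusteringRegime:
    """Partition from the ``rank``-th most prominent eigengap.

    ``labels`` holds one integer per feature; ``n_clusters`` equals the
    eigengap's eigenvalue index kappa_rank. Label values are arbitrary but
    deterministic; only the partition matters downstream.
    """

    rank: int
    n_clusters: int
    labels: np.ndarray

    def clusters(self) -> list[np.ndarray]:
        """Member-id arrays, one per cluster, ordered by label value."""
        order = np.argsort(self.labels, kind="stable")
        uniq, starts = np.unique(self.labels[order], return_index=True)
        return np.split(order, starts[1:])


def compute_affinity(S: np.ndarray) -> AffinityPair:
    """Pearson correlations between feature columns; affinity is |R|, diag 0.

    Raises on fewer than 3 samples or on any zero-variance feature (its
    correlations are undefined).
    """
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] < 3:
        raise ValueError("feature matrix must be 2-D with at least 3 samples")
    sd = S.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance feature(s) {dead.tolist()}: correlation undefined"
        )
    R = np.corrcoef(S, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    A = np.abs(R)
    np.fill_diagonal(A, 0.0)
    return AffinityPair(correlation=R, affinity=A)


def affinity_from_matrix(A: np.ndarray) -> AffinityPair:
    """Wrap a user-supplied symmetric affinity matrix (diagonal zeroed)."""
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if (A < 0).any():
        raise ValueError("affinity must be nonnegative")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    return AffinityPair(correlation=A.copy(), affinity=A)


def normalized_laplacian(ap: AffinityPair) -> Spectrum:
    """Degree matrix, Laplacian Q = D - A and symmetric normalization.

    Raises if any feature is isolated (zero degree): the normalization
    D^{-1/2} Q D^{-1/2} would be undefined.
    """
    A = ap.affinity
    deg = A.sum(axis=1)
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        raise ValueError(
            f"isolated feature(s) {isolated.tolist()}: zero degree"
        )
    Q = np.diag(deg) - A
    inv_sqrt = 1.0 / np.sqrt(deg)
    Qhat = Q * np.outer(inv_sqrt, inv_sqrt)
    Qhat = (Qhat + Qhat.T) / 2.0
    return Spectrum(degree=deg, laplacian=Q, norm_laplacian=Qhat)


def eigendecompose_and_rank(spec: Spectrum) -> Spectrum:
    """Ascending eigendecomposition plus eigengap prominence order.

    kappa ranking: eigenvalue indices 1..n-1 sorted by descending gap
    lam_{i+1} - lam_i, equal gaps resolved toward the smaller index.
    """
    lam, V = scipy.linalg.eigh(spec.norm_laplacian)
    gaps = np.diff(lam)
    # stable argsort of -gaps keeps the smaller index first among ties
    order = np.argsort(-gaps, kind="stable") + 1
    spec.eigenvalues = lam
    spec.eigenvectors = V
    spec.eigengaps = gaps
    spec.regime_order = order
    return spec


def cluster_qr(vectors: np.ndarray) -> np.ndarray:
    """QR-pivot label assignment on a spectral embedding.

    Column-pivoted QR of the transposed (n, k) eigenvector block picks k
    anchor rows; the SVD of the anchor block gives an orthogonal rotation,
    and each row is labeled by the arg-max absolute entry of its rotated
    embedding. Deterministic, and robust to eigenvector sign flips.
    """
    k = vectors.shape[1]
    _, _, piv = scipy.linalg.qr(vectors.T, pivoting=True)
    ut, _, vt = scipy.linalg.svd(vectors[piv[:k], :].T)
    rotated = np.abs(vectors @ (ut @ vt))
    return rotated.argmax(axis=1)


def cluster_regime(spec: Spectrum, rank: int) -> ClusteringRegime:
    """Partition for the ``rank``-th most prominent eigengap (1-based)."""
    if spec.regime_order is None:
        raise ValueError("spectrum not eigendecomposed yet")
    if not 1 <= rank <= len(spec.regime_order):
        raise ValueError(f"rank must be in [1, {len(spec.regime_order)}]")
    if rank in spec._regime_cache:
        return spec._regime_cache[rank]
    k = int(spec.regime_order[rank - 1])
    n = spec.n_features
    if k > n:
        raise ValueError(f"cluster count {k} exceeds feature count {n}")
    if k == 1:
        labels = np.zeros(n, dtype=np.intp)
    else:
        labels = cluster_qr(spec.eigenvectors[:, :k])
    regime = ClusteringRegime(rank=rank, n_clusters=k, labels=labels)
    spec._regime_cache[rank] = regime
    return regime


def top_regimes(spec: Spectrum, r: int) -> list[ClusteringRegime]:
    """Regimes for prominence ranks 1..r (cached per spectrum)."""
    if not 1 <= r <= spec.n_features - 1:
        raise ValueError(f"r must be in [1, {spec.n_features - 1}]")
    return [cluster_regime(spec, i) for i in range(1, r + 1)]
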