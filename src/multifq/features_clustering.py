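"""Feature extraction (PCA to a 3-D subspace) and k-means clustering.

Composite waveforms are mean-centered (NOT variance-scaled — bands keep
their native amplitude scale, since the composite splices raw filtered
waveforms) and projected onto the top principal components; the projections
are then partitioned with k-means.  Both steps are deterministic given the
seed, and a deterministic sign convention (the largest-|loading| entry of
each eigenvector is positive) removes PCA's sign ambiguity.

The backend protocol at the bottom lets third-party feature extractors
(N x M -> N x d) and clusterers (N x d -> labels) slot into the pipeline in
place of PCA / k-means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Protocol, Union, runtime_checkable

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .detection import CompositeWaveforms

__all__ = [
    "FeatureMatrix",
    "ClusterLabels",
    "pca_fit_transform",
    "kmeans_cluster",
    "FeatureExtractor",
    "Clusterer",
    "PCAFeatures",
    "KMeansClusterer",
]

MatrixLike = Union[np.ndarray, CompositeWaveforms]


def _as_matrix(data: MatrixLike) -> np.ndarray:
    if isinstance(data, CompositeWaveforms):
        return data.matrix
    return np.asarray(data, dtype=np.float64)


@dataclass(frozen=True)
class FeatureMatrix:
    """Component scores plus the information needed to interpret them.

    ``scores`` is N x d; ``explained_variance`` holds the d covariance
    eigenvalues in non-increasing order; ``mean_vector`` is the subtracted
    column mean; ``components`` the (sign-fixed) eigenvector rows.
    """

    scores: np.ndarray
    explained_variance: np.ndarray
    mean_vector: np.ndarray
    components: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.scores.shape[0])

    @property
    def d(self) -> int:
        return int(self.scores.shape[1])


def pca_fit_transform(composite: MatrixLike, d: int = 3) -> FeatureMatrix:
    """Project waveforms onto the top-``d`` principal components.

    Columns are mean-centered only; components are ordered by non-increasing
    explained variance and sign-fixed so each eigenvector's largest-|loading|
    entry is positive.
    """
    X = _as_matrix(composite)
    n, m = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 waveforms")
    if d < 1 or d > min(n, m):
        raise ValueError(f"component count d={d} must lie in 1..min(N={n}, M={m})")
    pca = PCA(n_components=d, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    for c in range(d):
        j = int(np.argmax(np.abs(components[c])))
        if components[c, j] < 0:
            components[c] *= -1.0
            scores[:, c] *= -1.0
    return FeatureMatrix(
        scores=scores,
        explained_variance=pca.explained_variance_.copy(),
        mean_vector=pca.mean_.copy(),
        components=components,
    )


@dataclass(frozen=True)
class ClusterLabels:
    """A k-means partition: integer labels in 0..K-1 with final inertia."""

    labels: np.ndarray
    K: int
    inertia: float
    seed: Optional[int]

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.size and (lab.min() < 0 or lab.max() >= self.K):
            raise ValueError("labels must lie in 0..K-1")
        object.__setattr__(self, "labels", lab)

    @property
    def empty_clusters(self) -> tuple[int, ...]:
        present = set(np.unique(self.labels).tolist())
        return tuple(k for k in range(self.K) if k not in present)


FeaturesLike = Union[np.ndarray, FeatureMatrix]


def _as_features(features: FeaturesLike) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.scores
    return np.asarray(features, dtype=np.float64)


def kmeans_cluster(
    features: FeaturesLike,
    K: int,
    seed: Optional[int] = 0,
    restarts: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> ClusterLabels:
    """Partition feature vectors into K clusters (best of ``restarts`` runs).

    Greedy (k-means++-style) seeding; iteration stops when assignments are
    unchanged or center movement falls below ``tol``; the run with the lowest
    within-cluster sum of squares wins.  Reproducible given (seed, restarts).
    """
    X = _as_features(features)
    n = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of points N={n}")
    km = KMeans(
        n_clusters=K,
        init="k-means++",
        n_init=restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    labels = km.fit_predict(X)
    return ClusterLabels(labels=labels, K=K, inertia=float(km.inertia_), seed=seed)


@runtime_checkable
class FeatureExtractor(Protocol):
    """Backend protocol: map an N x M waveform matrix to N x d features."""

    def __call__(self, waveforms: np.ndarray) -> np.ndarray: ...


@runtime_checkable
class Clusterer(Protocol):
    """Backend protocol: map an N x d feature matrix to N integer labels."""

    def __call__(self, features: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class PCAFeatures:
    """Default feature backend: top-d PCA scores."""

    d: int = 3

    def __call__(self, waveforms: np.ndarray) -> np.ndarray:
        return pca_fit_transform(waveforms, d=self.d).scores


@dataclass(frozen=True)
class KMeansClusterer:
    """Default clustering backend: seeded k-means, best of ``restarts``."""

    K: int
    seed: Optional[int] = 0
    restarts: int = 10

    def __call__(self, features: np.ndarray) -> np.ndarray:
        return kmeans_cluster(features, K=self.K, seed=self.seed, restarts=self.restarts).labels
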