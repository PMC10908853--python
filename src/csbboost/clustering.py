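"""Per-class K-means clustering and silhouette-based choice of K.

K-means (k-means++ seeding, multiple restarts, best inertia) partitions one
class into K clusters; the silhouette coefficient

    s(i) = (b(i) - a(i)) / max(a(i), b(i))

with a(i) the mean distance from point i to its own cluster's other members
and b(i) the smallest mean distance to another cluster, scores each candidate
K, and the K with the largest mean silhouette wins (ties go to the smaller K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = ["ClusterModel", "SilhouetteSummary", "KSelection", "kmeans",
           "silhouette_values", "select_k"]


@dataclass
class ClusterModel:
    K: int
    centroids: np.ndarray          # K x d
    assignments: np.ndarray        # length n, values in [0, K)
    inertia: float                 # sum of squared distances to assigned centroid
    seed: int

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.K)

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "centroids": self.centroids.tolist(),
            "assignments": self.assignments.tolist(),
            "inertia": float(self.inertia),
            "seed": int(self.seed),
        }


@dataclass
class SilhouetteSummary:
    """Per-point silhouette values with their a(i)/b(i) components."""

    per_point: np.ndarray
    mean: float
    K: int
    a_values: np.ndarray
    b_values: np.ndarray


@dataclass
class KSelection:
    best_k: int
    summaries: list[SilhouetteSummary] = field(default_factory=list)
    degenerate: bool = False

    @property
    def mean_by_k(self) -> dict[int, float]:
        return {s.K: s.mean for s in self.summaries}


def kmeans(
    X: np.ndarray,
    K: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    init="k-means++",
) -> ClusterModel:
    """K-means with k-means++ seeding, best of ``n_init`` restarts by inertia.

    ``init`` may be an explicit K x d centroid array (then a single run is
    performed), which makes the procedure fully deterministic for tests.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if d == 0:
        raise ValueError("kmeans requires at least one feature")
    if not 1 <= K <= n:
        raise ValueError(f"K={K} outside [1, n={n}]")
    if isinstance(init, np.ndarray):
        n_init = 1
    km = KMeans(
        n_clusters=K,
        init=init,
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=int(seed) % 2**31,
    ).fit(X)
    return ClusterModel(
        K=K,
        centroids=km.cluster_centers_,
        assignments=km.labels_.astype(int),
        inertia=float(km.inertia_),
        seed=int(seed),
    )


def silhouette_values(X: np.ndarray, assignments: np.ndarray) -> SilhouetteSummary:
    """Silhouette coefficient of every point, with a(i) and b(i) retained.

    Singleton clusters contribute s(i) = 0 (the within-cluster mean distance
    is undefined with no co-members); coincident points where a = b = 0 also
    score 0.
    """
    X = np.asarray(X, dtype=float)
    assignments = np.asarray(assignments, dtype=int)
    n = X.shape[0]
    if n < 3:
        raise ValueError("silhouette needs at least 3 points")
    clusters, inverse = np.unique(assignments, return_inverse=True)
    K = clusters.size
    if K < 2:
        raise ValueError("silhouette requires at least two clusters")
    sizes = np.bincount(inverse, minlength=K)

    D = cdist(X, X)
    # sums[i, c] = total distance from point i to all members of cluster c
    member = np.eye(K)[inverse]                     # n x K indicator
    sums = D @ member

    own = sums[np.arange(n), inverse]
    own_size = sizes[inverse]
    a = np.zeros(n)
    multi = own_size > 1
    a[multi] = own[multi] / (own_size[multi] - 1)

    mean_to = sums / sizes[np.newaxis, :]
    mean_to[np.arange(n), inverse] = np.inf
    b = mean_to.min(axis=1)

    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = (denom > 0) & multi
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return SilhouetteSummary(
        per_point=s, mean=float(s.mean()), K=K, a_values=a, b_values=b
    )


def select_k(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int | None = None,
    seed: int = 0,
    n_init: int = 10,
) -> KSelection:
    """Sweep K in [k_min, k_max], return the K maximising mean silhouette.

    The default sweep cap min(10, n // 5) keeps at least five points per
    cluster on average. Too few points to cluster (n < 2 * k_min) degrades to
    K = 1 with no summaries. Ties in mean silhouette favour the smaller K.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2 * k_min:
        return KSelection(best_k=1, summaries=[], degenerate=True)
    if k_max is None:
        k_max = max(k_min, min(10, n // 5))
    k_max = min(k_max, n - 1)
    if k_min > k_max:
        raise ValueError(f"k_min={k_min} exceeds k_max={k_max}")

    summaries: list[SilhouetteSummary] = []
    best_k, best_mean = None, -np.inf
    for K in range(k_min, k_max + 1):
        model = kmeans(X, K, seed=seed, n_init=n_init)
        summ = silhouette_values(X, model.assignments)
        summ.K = K
        summaries.append(summ)
        if summ.mean > best_mean + 1e-15:
            best_k, best_mean = K, summ.mean
    return KSelection(best_k=int(best_k), summaries=summaries)
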