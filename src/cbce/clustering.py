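"""Random-subspace k-means used to build one cluster collection.

Each base classifier clusters the full training set with Lloyd's algorithm,
but measures distance only over a randomly drawn feature subset.  Retained
clusters report a *full-dimension* centroid (per-feature mean, or per-feature
mode for binary data) plus exact per-class membership counts, which downstream
code converts into class-support values.

The randomisation contract: the subset size l is uniform on [1, L], the l
indices are drawn uniformly *with replacement* and then deduplicated (the raw
draw is kept for logging — duplicates carry no weighting semantics here), and
the cluster count P is uniform on [M, mult·M] with mult defaulting to 3; the
upper bound exists to keep empty clusters rare, not impossible, so empty
clusters at convergence are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FeatureSubset",
    "ClusterModel",
    "sample_feature_subset",
    "sample_cluster_count",
    "subspace_kmeans",
    "euclidean",
    "squared_euclidean",
]

logger = logging.getLogger(__name__)

MAX_LLOYD_ITERATIONS = 100


@dataclass(frozen=True)
class FeatureSubset:
    """A deduplicated set of feature indices plus the raw sampled draw."""

    indices: tuple[int, ...]
    raw_draw: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError("feature subset cannot be empty")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("subset indices must be deduplicated")

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class ClusterModel:
    """One retained cluster: full-dimension centroid and class membership.

    ``class_counts[j]`` is the exact number of member instances of class j
    (in the data matrix's class order); their sum is the cluster size.
    """

    index: int
    centroid: np.ndarray
    class_counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        object.__setattr__(self, "class_counts",
                           np.asarray(self.class_counts, dtype=int))
        if self.size < 1:
            raise ValueError("retained clusters must be non-empty")

    @property
    def size(self) -> int:
        return int(self.class_counts.sum())


def sample_feature_subset(n_features: int, rng: np.random.Generator) -> FeatureSubset:
    """Draw l ~ U[1, L] indices uniformly with replacement, deduplicated."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    size = int(rng.integers(1, n_features + 1))
    raw = rng.integers(0, n_features, size=size)
    return FeatureSubset(tuple(sorted(set(int(i) for i in raw))),
                         tuple(int(i) for i in raw))


def sample_cluster_count(n_classes: int, rng: np.random.Generator,
                         bound_multiplier: int = 3) -> int:
    """Draw the cluster count uniformly on [M, bound_multiplier * M]."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    if bound_multiplier < 1:
        raise ValueError("bound multiplier must be >= 1")
    return int(rng.integers(n_classes, bound_multiplier * n_classes + 1))


def euclidean(a: np.ndarray, b: np.ndarray,
              subset: FeatureSubset | None = None) -> float:
    """Euclidean distance, optionally restricted to a feature subset."""
    return float(np.sqrt(squared_euclidean(a, b, subset)))


def squared_euclidean(a: np.ndarray, b: np.ndarray,
                      subset: FeatureSubset | None = None) -> float:
    """Squared Euclidean distance (handy for expository comparisons)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if subset is not None:
        idx = list(subset.indices)
        a, b = a[idx], b[idx]
    diff = a - b
    return float(diff @ diff)


def _centroids(X: np.ndarray, assign: np.ndarray, P: int, mode: bool) -> np.ndarray:
    """Full-dimension centroids; empty clusters yield NaN rows."""
    L = X.shape[1]
    out = np.full((P, L), np.nan)
    for i in range(P):
        members = X[assign == i]
        if len(members) == 0:
            continue
        if mode:
            # per-feature mode; ties broken toward the smaller value
            out[i] = np.array([
                np.bincount(members[:, f].astype(int)).argmax()
                for f in range(L)
            ], dtype=float)
        else:
            out[i] = members.mean(axis=0)
    return out


def subspace_kmeans(X: np.ndarray, class_idx: np.ndarray, n_classes: int,
                    subset: FeatureSubset, n_clusters: int,
                    rng: np.random.Generator,
                    centroid_mode: str = "mean") -> list[ClusterModel]:
    """Lloyd's algorithm with distances restricted to ``subset``.

    Parameters
    ----------
    X : (N, L) data matrix; ``class_idx`` gives each row's class index.
    subset : the feature subset defining the clustering metric.
    n_clusters : P, the number of seeds; ``P > N`` is an error since seeds are
        P distinct instances drawn uniformly without replacement.
    centroid_mode : ``"mean"`` (arithmetic mean) or ``"mode"`` (per-feature
        mode, for binary/categorical data — centroids stay 0/1).

    Returns the retained (non-empty) clusters with full-dimension centroids
    and per-class counts.  Assignment ties go to the lowest cluster index;
    convergence is unchanged assignments or a 100-iteration cap.
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if n_clusters > N:
        raise ValueError(
            f"cannot seed {n_clusters} clusters from {N} instances"
        )
    if centroid_mode not in ("mean", "mode"):
        raise ValueError(f"unknown centroid mode {centroid_mode!r}")
    use_mode = centroid_mode == "mode"
    cols = list(subset.indices)
    Xs = X[:, cols]

    seed_rows = rng.choice(N, size=n_clusters, replace=False)
    centroids = X[seed_rows].astype(float).copy()

    assign = np.full(N, -1, dtype=int)
    for iteration in range(MAX_LLOYD_ITERATIONS):
        live = ~np.isnan(centroids[:, 0])
        d = cdist(Xs, centroids[live][:, cols])
        new_assign = np.flatnonzero(live)[d.argmin(axis=1)]
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        centroids = _centroids(X, assign, n_clusters, use_mode)
    n_iterations = iteration + 1

    clusters = []
    dropped = 0
    for i in range(n_clusters):
        members = assign == i
        if not members.any():
            dropped += 1
            continue
        counts = np.bincount(class_idx[members], minlength=n_classes)
        clusters.append(ClusterModel(len(clusters), centroids[i], counts))
    logger.debug(
        "k-means: P=%d subset=%d dims, %d iterations, %d empty dropped",
        n_clusters, subset.size, n_iterations, dropped,
    )
    return clusters
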