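"""Cluster-based classifier ensemble: training and support fusion.

One *base classifier* is a collection of k-means clusters built on a random
feature subset, summarised by a support matrix A whose entry A[i, j] in
[-1, 1] measures how strongly membership of cluster i supports class j:

    A[i, j] = (N_ij - N_i/M) / (N_i - N_i/M)   if N_ij >= N_i/M
    A[i, j] = (N_ij - N_i/M) / (N_i/M)         otherwise

where N_i is the cluster size, N_ij its count of class-j members and M the
number of classes; N_i/M is the count a class would have if the cluster were
perfectly mixed.  A pure cluster scores 1 for its class, an absent class
scores -1, a perfectly mixed cluster scores 0 everywhere.

Classification picks the nearest cluster (full-space Euclidean distance to
the centroid) from each of the K collections and fuses the selected support
rows into a per-class score

    ExSupp(c_j) = sum over classifiers k of  exp(A_k[i_k, j] / (1 + d_k))

with contributions from A = -1 entries excluded (exactly 0).  The predicted
class is the argmax; distance damps the exponent, so a nearby cluster pulls
the score toward e^{A} while a distant one pulls it toward e^0 = 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .clustering import (
    ClusterModel,
    FeatureSubset,
    sample_cluster_count,
    sample_feature_subset,
    subspace_kmeans,
)
from .encoding import DataMatrix, FeatureVector, SensorInventory

__all__ = [
    "CBCEConfig",
    "BaseClassifier",
    "Ensemble",
    "SupportVector",
    "ClassifierTrace",
    "compute_support_matrix",
    "train_base_classifier",
    "train_ensemble",
    "nearest_cluster",
    "class_support",
    "predict",
    "predict_matrix",
]

logger = logging.getLogger(__name__)

PERSISTENCE_FORMAT_VERSION = 1


@dataclass(frozen=True)
class CBCEConfig:
    """Training-time knobs.

    n_classifiers : ensemble size K (default 30 — large enough that the
        random subset/cluster-count draws average out; see the stability
        experiment in :mod:`cbce.evaluation`).
    cluster_bound_multiplier : the per-classifier cluster count is drawn
        uniformly from [M, multiplier * M]; the upper bound keeps empty
        clusters rare.
    centroid_mode : "mean", "mode", or "auto" (mode for binary-encoded data,
        mean for numeric).
    """

    n_classifiers: int = 30
    cluster_bound_multiplier: int = 3
    centroid_mode: str = "auto"

    def __post_init__(self) -> None:
        if self.n_classifiers < 1:
            raise ValueError("ensemble size must be >= 1")
        if self.cluster_bound_multiplier < 1:
            raise ValueError("cluster bound multiplier must be >= 1")
        if self.centroid_mode not in ("mean", "mode", "auto"):
            raise ValueError(f"unknown centroid mode {self.centroid_mode!r}")

    def resolve_centroid_mode(self, encoding: str) -> str:
        if self.centroid_mode != "auto":
            return self.centroid_mode
        return "mode" if encoding == "binary" else "mean"


@dataclass(frozen=True)
class BaseClassifier:
    """One cluster collection with its support matrix.

    ``support`` has one row per retained cluster, aligned with ``clusters``;
    entries lie in [-1, 1] with at least one entry > -1 per row.
    """

    index: int
    subset: FeatureSubset
    clusters: tuple[ClusterModel, ...]
    support: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "clusters", tuple(self.clusters))
        s = np.asarray(self.support, dtype=float)
        if s.shape[0] != len(self.clusters):
            raise ValueError("support rows must align 1:1 with clusters")
        if len(self.clusters) == 0:
            raise ValueError("a base classifier needs at least one cluster")
        if (s < -1).any() or (s > 1).any():
            raise ValueError("support values must lie in [-1, 1]")
        object.__setattr__(self, "support", s)
        s.setflags(write=False)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def centroid_matrix(self) -> np.ndarray:
        """(P, L) stack of retained-cluster centroids (cached)."""
        cached = getattr(self, "_centroid_matrix", None)
        if cached is None:
            cached = np.array([c.centroid for c in self.clusters])
            object.__setattr__(self, "_centroid_matrix", cached)
        return cached


@dataclass(frozen=True)
class Ensemble:
    """K base classifiers sharing one class ordering and feature layout."""

    classifiers: tuple[BaseClassifier, ...]
    classes: tuple[str, ...]
    inventory: SensorInventory
    encoding: str
    majority_class: str
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "classifiers", tuple(self.classifiers))
        object.__setattr__(self, "classes", tuple(self.classes))
        if len(self.classifiers) < 1:
            raise ValueError("ensemble needs at least one base classifier")
        M = len(self.classes)
        for bc in self.classifiers:
            if bc.support.shape[1] != M:
                raise ValueError("support matrix width must equal class count")
        if self.majority_class not in self.classes:
            raise ValueError("majority class must be one of the classes")

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format_version": PERSISTENCE_FORMAT_VERSION,
            "classes": list(self.classes),
            "inventory": list(self.inventory.labels),
            "encoding": self.encoding,
            "majority_class": self.majority_class,
            "seed": self.seed,
            "classifiers": [
                {
                    "index": bc.index,
                    "seed": bc.seed,
                    "subset": list(bc.subset.indices),
                    "subset_raw_draw": list(bc.subset.raw_draw),
                    "clusters": [
                        {
                            "centroid": c.centroid.tolist(),
                            "class_counts": c.class_counts.tolist(),
                        }
                        for c in bc.clusters
                    ],
                    "support": bc.support.tolist(),
                }
                for bc in self.classifiers
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "Ensemble":
        doc = json.loads(text)
        version = doc.get("format_version")
        if version != PERSISTENCE_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version: {version}")
        classifiers = tuple(
            BaseClassifier(
                index=bc["index"],
                subset=FeatureSubset(tuple(bc["subset"]),
                                     tuple(bc["subset_raw_draw"])),
                clusters=tuple(
                    ClusterModel(i, np.array(c["centroid"], dtype=float),
                                 np.array(c["class_counts"], dtype=int))
                    for i, c in enumerate(bc["clusters"])
                ),
                support=np.array(bc["support"], dtype=float),
                seed=bc["seed"],
            )
            for bc in doc["classifiers"]
        )
        return cls(
            classifiers=classifiers,
            classes=tuple(doc["classes"]),
            inventory=SensorInventory(tuple(doc["inventory"])),
            encoding=doc["encoding"],
            majority_class=doc["majority_class"],
            seed=doc["seed"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "Ensemble":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class ClassifierTrace:
    """Per-classifier record of one fusion: which cluster, how far, what it
    contributed to each class."""

    classifier: int
    cluster: int
    distance: float
    support_row: np.ndarray
    contributions: np.ndarray


@dataclass(frozen=True)
class SupportVector:
    """Fused per-class supports plus the per-classifier trace."""

    values: np.ndarray
    classes: tuple[str, ...]
    trace: tuple[ClassifierTrace, ...] = field(default=(), repr=False)

    def as_dict(self) -> dict[str, float]:
        return {c: float(v) for c, v in zip(self.classes, self.values)}

    def best(self) -> str | None:
        """Highest-support class, or None if every class scored 0."""
        if self.values.max() <= 0.0:
            return None
        return self.classes[int(np.argmax(self.values))]


def compute_support_matrix(clusters: Sequence[ClusterModel] | np.ndarray,
                           n_classes: int | None = None) -> np.ndarray:
    """Per-cluster class-support values from membership counts.

    Accepts retained clusters or a plain (P, M) count array.  Full precision
    throughout; rounding is a display concern.  With a single class every
    cluster is pure by construction, so the support is defined as 1.
    """
    if isinstance(clusters, np.ndarray):
        counts = np.asarray(clusters, dtype=float)
    else:
        counts = np.array([c.class_counts for c in clusters], dtype=float)
    if counts.ndim != 2:
        raise ValueError("expected a (clusters x classes) count grid")
    if n_classes is not None and counts.shape[1] != n_classes:
        raise ValueError(
            f"count grid has {counts.shape[1]} classes, expected {n_classes}"
        )
    M = counts.shape[1]
    sizes = counts.sum(axis=1, keepdims=True)
    if (sizes < 1).any():
        raise ValueError("empty clusters must be dropped before support")
    if M == 1:
        return np.ones_like(counts)
    mixed = sizes / M  # per-class count of a perfectly mixed cluster
    excess = counts - mixed
    above = excess / (sizes - mixed)
    below = excess / mixed
    return np.where(excess >= 0, above, below)


def _classifier_rng(master_seed: int | None, k: int) -> tuple[np.random.Generator, int]:
    """Deterministic per-classifier generator derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(k,))
    child_seed = int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)
    return np.random.Generator(np.random.PCG64(ss)), child_seed


def train_base_classifier(data: DataMatrix, k: int,
                          config: CBCEConfig = CBCEConfig(),
                          seed: int | None = None) -> BaseClassifier:
    """Train classifier k: draw subset and cluster count, cluster, score.

    All randomness flows from the (master seed, k) pair, so retraining with
    the same seed reproduces the classifier bit for bit.
    """
    rng, child_seed = _classifier_rng(seed, k)
    L, M, N = data.n_features, data.n_classes, data.n_instances
    subset = sample_feature_subset(L, rng)
    n_clusters = sample_cluster_count(M, rng, config.cluster_bound_multiplier)
    n_clusters = min(n_clusters, N)  # cannot seed more centroids than instances
    clusters = subspace_kmeans(
        data.X, data.class_index(), M, subset, n_clusters, rng,
        config.resolve_centroid_mode(data.encoding),
    )
    support = compute_support_matrix(clusters, M)
    logger.info(
        "base classifier %d: |subset|=%d, P=%d, retained=%d",
        k, subset.size, n_clusters, len(clusters),
    )
    return BaseClassifier(k, subset, tuple(clusters), support, child_seed)


def train_ensemble(data: DataMatrix, config: CBCEConfig = CBCEConfig(),
                   seed: int | None = None) -> Ensemble:
    """Train K independent base classifiers and record the majority class."""
    if data.n_instances < data.n_classes:
        raise ValueError("need at least as many instances as classes")
    classifiers = tuple(
        train_base_classifier(data, k, config, seed)
        for k in range(config.n_classifiers)
    )
    labels, freq = np.unique(data.y, return_counts=True)
    majority = str(labels[np.argmax(freq)])
    logger.info("trained ensemble: K=%d, M=%d, N=%d, majority=%r",
                len(classifiers), data.n_classes, data.n_instances, majority)
    return Ensemble(classifiers, data.classes, data.inventory, data.encoding,
                    majority, seed)


def _query_values(x: FeatureVector | np.ndarray) -> np.ndarray:
    return x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)


def nearest_cluster(x: FeatureVector | np.ndarray,
                    classifier: BaseClassifier) -> tuple[int, float]:
    """Nearest retained cluster by full-space Euclidean distance.

    The per-classifier subspace shapes training only; queries are compared to
    the full-dimension centroids.  Ties go to the lowest cluster index.
    """
    v = _query_values(x)
    centroids = classifier.centroid_matrix
    if v.shape[0] != centroids.shape[1]:
        raise ValueError(
            f"query length {v.shape[0]} != feature count {centroids.shape[1]}"
        )
    d = np.sqrt(((centroids - v) ** 2).sum(axis=1))
    i = int(d.argmin())  # argmin takes the first minimum: lowest index on ties
    return i, float(d[i])


def class_support(x: FeatureVector | np.ndarray, ensemble: Ensemble) -> SupportVector:
    """Fuse the selected support rows into per-class exponential scores."""
    v = _query_values(x)
    M = ensemble.n_classes
    totals = np.zeros(M)
    trace = []
    for bc in ensemble.classifiers:
        i, d = nearest_cluster(v, bc)
        row = bc.support[i]
        contrib = np.where(row > -1.0, np.exp(row / (1.0 + d)), 0.0)
        totals += contrib
        trace.append(ClassifierTrace(bc.index, i, d, row, contrib))
    return SupportVector(totals, ensemble.classes, tuple(trace))


def predict(x: FeatureVector | np.ndarray, ensemble: Ensemble) -> str:
    """Highest fused support wins; ties go to the earlier class in the
    ensemble's class order, and an all-zero support vector falls back to the
    training-majority class."""
    best = class_support(x, ensemble).best()
    return best if best is not None else ensemble.majority_class


def predict_matrix(data: DataMatrix | np.ndarray, ensemble: Ensemble) -> np.ndarray:
    """Vector of predictions for every row of a matrix."""
    X = data.X if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    return np.array([predict(row, ensemble) for row in X], dtype=object)
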