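"""A bundled, fully specified example ensemble over the default inventory.

Three cluster collections (13, 11 and 7 clusters) for the seven-activity
smart-apartment problem, with hand-specified binary centroids, per-class
membership counts and support matrices.  The support matrices are stated at
display precision (one to two decimals), as they would appear in a report,
and are used as-is; the membership counts allow the full-precision support
values to be recomputed independently.

The fixture makes exact-arithmetic demonstrations possible without any
training: classifying :data:`DEMO_QUERY` selects clusters 1, 8 and 5 from the
three collections at distances √3, 1 and 1 and yields the label
``"prepare-dinner"``.  It also backs CLI smoke tests and the documentation
walk-through.
"""

from __future__ import annotations

import numpy as np

from .clustering import ClusterModel, FeatureSubset
from .encoding import FeatureVector, default_inventory
from .ensemble import BaseClassifier, Ensemble

__all__ = [
    "DEMO_CLASSES",
    "DEMO_QUERY",
    "demo_ensemble",
    "demo_cluster_counts",
    "demo_support_matrices",
]

#: Class ordering shared by all three collections.
DEMO_CLASSES: tuple[str, ...] = (
    "go-to-bed",
    "use-toilet",
    "prepare-breakfast",
    "take-shower",
    "get-drink",
    "prepare-dinner",
    "leave-house",
)

#: A query instance (binary encoding): Plates cupboard + Freezer activated.
DEMO_QUERY = FeatureVector(
    np.array([0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0], dtype=float),
    "binary",
)

# Each collection: list of (centroid, class counts, display-precision support).
_COLLECTIONS = [
    [  # collection 1 — 13 clusters
        ([0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], [14, 0, 0, 17, 0, 2, 0],
         [0.3, -1, -1, 0.4, -1, -0.6, -1]),
        ([0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0, 25],
         [-1, -1, -1, -1, -1, -1, 1]),
        ([0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0], [0, 69, 0, 0, 0, 0, 0],
         [-1, 1, -1, -1, -1, -1, -1]),
        ([0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0, 0, 1, 0, 12, 0, 0],
         [-1, -1, -0.5, -1, 0.9, -1, -1]),
        ([0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0], [0, 0, 16, 0, 2, 0, 0],
         [-1, -1, 0.9, -1, -0.2, -1, -1]),
        ([0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 1, 0, 0],
         [-1, -1, -1, -1, 1, -1, -1]),
        ([0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0], [0, 13, 0, 0, 0, 0, 0],
         [-1, 1, -1, -1, -1, -1, -1]),
        ([0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0, 10, 0, 1, 0, 0, 0],
         [-1, 0.9, -1, -0.4, -1, -1, -1]),
        ([1, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 0, 1, 0], [0, 0, 1, 0, 0, 3, 0],
         [-1, -1, 0.1, -1, -1, 0.7, -1]),
        ([0, 0, 0, 1, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0], [0, 0, 0, 0, 0, 1, 0],
         [-1, -1, -1, -1, -1, 1, -1]),
        ([0, 0, 0, 1, 1, 0, 0, 1, 0, 1, 0, 0, 0, 0], [0, 0, 0, 0, 1, 0, 0],
         [-1, -1, -1, -1, 1, -1, -1]),
        ([0, 0, 0, 0, 1, 1, 0, 0, 0, 1, 1, 0, 1, 0], [0, 0, 0, 0, 0, 2, 0],
         [-1, -1, -1, -1, -1, 1, -1]),
        ([0, 0, 0, 0, 1, 1, 0, 1, 0, 1, 1, 0, 0, 0], [0, 0, 1, 0, 0, 0, 0],
         [-1, -1, 1, -1, -1, -1, -1]),
    ],
    [  # collection 2 — 11 clusters
        ([0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1], [14, 0, 0, 0, 0, 0, 0],
         [1, -1, -1, -1, -1, -1, -1]),
        ([0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0, 2, 1, 18, 0, 0, 0],
         [-1, -0.3, -0.7, 0.8, -1, -1, -1]),
        ([0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0, 24],
         [-1, -1, -1, -1, -1, -1, 1]),
        ([0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0], [0, 74, 0, 0, 0, 0, 0],
         [-1, 1, -1, -1, -1, -1, -1]),
        ([0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0, 1],
         [-1, -1, -1, -1, -1, -1, 1]),
        ([0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0, 0, 2, 0, 13, 3, 0],
         [-1, -1, -0.2, -1, 0.7, 0.03, -1]),
        ([0, 1, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0], [0, 11, 0, 0, 0, 0, 0],
         [-1, 1, -1, -1, -1, -1, -1]),
        ([1, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 0, 0], [0, 0, 2, 0, 0, 2, 0],
         [-1, -1, 0.4, -1, -1, 0.4, -1]),
        ([0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0], [0, 0, 14, 0, 2, 2, 0],
         [-1, -1, 0.7, -1, -0.2, -0.2, -1]),
        ([0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 1, 1, 0],
         [-1, -1, -1, -1, 0.4, 0.4, -1]),
        ([0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0], [0, 5, 0, 0, 0, 0, 0],
         [-1, 1, -1, -1, -1, -1, -1]),
    ],
    [  # collection 3 — 7 clusters
        ([0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1], [9, 3, 0, 0, 0, 0, 0],
         [0.7, 0.1, -1, -1, -1, -1, -1]),
        ([0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0, 18, 0, 18, 0, 0, 1],
         [-1, 0.4, -1, 0.4, -1, -1, -0.8]),
        ([0, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0], [0, 71, 0, 0, 1, 0, 24],
         [-1, 0.7, -1, -1, -0.9, -1, 0.1]),
        ([0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0], [0, 0, 1, 0, 15, 0, 0],
         [-1, -1, -0.6, -1, 0.9, -1, -1]),
        ([0, 0, 0, 0, 0, 1, 0, 0, 0, 1, 0, 0, 1, 0], [0, 0, 0, 0, 0, 3, 0],
         [-1, -1, -1, -1, -1, 1, -1]),
        ([0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0], [0, 0, 18, 0, 0, 5, 0],
         [-1, -1, 0.8, -1, -1, 0.1, -1]),
        ([0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1], [5, 0, 0, 0, 0, 0, 0],
         [1, -1, -1, -1, -1, -1, -1]),
    ],
]


def demo_cluster_counts() -> list[np.ndarray]:
    """Per-collection (clusters × classes) membership-count grids."""
    return [np.array([counts for _, counts, _ in coll], dtype=int)
            for coll in _COLLECTIONS]


def demo_support_matrices() -> list[np.ndarray]:
    """Per-collection support matrices at their stated display precision."""
    return [np.array([support for _, _, support in coll], dtype=float)
            for coll in _COLLECTIONS]


def demo_ensemble() -> Ensemble:
    """Build the three-classifier example ensemble.

    The feature subsets drawn during the original clustering are not part of
    the fixture (classification never consults them), so each classifier
    records the full feature set as its subset.
    """
    inventory = default_inventory()
    full = FeatureSubset(tuple(range(len(inventory))),
                         tuple(range(len(inventory))))
    classifiers = []
    for k, coll in enumerate(_COLLECTIONS):
        clusters = tuple(
            ClusterModel(i, np.array(centroid, dtype=float),
                         np.array(counts, dtype=int))
            for i, (centroid, counts, _) in enumerate(coll)
        )
        support = np.array([support for _, _, support in coll], dtype=float)
        classifiers.append(BaseClassifier(k, full, clusters, support))
    return Ensemble(tuple(classifiers), DEMO_CLASSES, inventory, "binary",
                    majority_class="use-toilet")
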