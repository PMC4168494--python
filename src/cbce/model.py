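"""Model/Results front end over the ensemble machinery.

``CBCEModel`` binds a training :class:`~cbce.encoding.DataMatrix` to the
training knobs; ``fit`` trains the ensemble and returns a ``CBCEResults``
carrying the fitted ensemble, per-classifier diagnostics and prediction /
evaluation / persistence methods.  This mirrors how statistical modelling
packages separate a model specification from a fitted result.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoding import DataMatrix, FeatureVector, SensorInventory
from .ensemble import (
    CBCEConfig,
    Ensemble,
    SupportVector,
    class_support,
    predict,
    predict_matrix,
    train_ensemble,
)
from .evaluation import ConfusionMatrix, MetricsReport, metrics_from_confusion

__all__ = ["CBCEModel", "CBCEResults"]


class CBCEModel:
    """Cluster-based classifier ensemble specification bound to data.

    Parameters
    ----------
    data : training matrix (instances × sensors with class labels).
    n_classifiers : ensemble size K (default 30).
    cluster_bound_multiplier : per-classifier cluster counts are drawn
        uniformly from [M, multiplier·M], M the number of classes.
    centroid_mode : "mean", "mode" or "auto" (mode for binary data).
    """

    def __init__(self, data: DataMatrix, n_classifiers: int = 30,
                 cluster_bound_multiplier: int = 3,
                 centroid_mode: str = "auto") -> None:
        self.data = data
        self.config = CBCEConfig(n_classifiers, cluster_bound_multiplier,
                                 centroid_mode)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, encoding: str | None = None,
                       class_col: str = "class",
                       classes: Sequence[str] | None = None,
                       **config) -> "CBCEModel":
        """Build from a DataFrame whose non-class columns are sensor counts."""
        if class_col not in df.columns:
            raise ValueError(f"no {class_col!r} column in frame")
        features = df.drop(columns=[class_col])
        X = features.to_numpy(dtype=float)
        if encoding is None:
            encoding = "binary" if np.isin(X, (0.0, 1.0)).all() else "numeric"
        data = DataMatrix(
            X, df[class_col].astype(str).to_numpy(dtype=object),
            SensorInventory(tuple(str(c) for c in features.columns)),
            encoding, tuple(classes) if classes is not None else (),
        )
        return cls(data, **config)

    def fit(self, seed: int | None = None) -> "CBCEResults":
        """Train the K base classifiers (deterministic given ``seed``)."""
        ensemble = train_ensemble(self.data, self.config, seed)
        return CBCEResults(self, ensemble)


@dataclass
class CBCEResults:
    """A fitted ensemble with diagnostics.

    ``diagnostics`` has one row per base classifier: subset size, requested
    vs retained cluster count, and the share of pure clusters — a quick view
    of how specialised each collection is.
    """

    model: CBCEModel | None
    ensemble: Ensemble

    def predict(self, X) -> np.ndarray:
        """Predicted activity labels for a matrix (or DataMatrix) of queries."""
        return predict_matrix(X, self.ensemble)

    def predict_one(self, x: FeatureVector | np.ndarray) -> str:
        return predict(x, self.ensemble)

    def support(self, x: FeatureVector | np.ndarray) -> SupportVector:
        """Fused per-class supports for one query, with the fusion trace."""
        return class_support(x, self.ensemble)

    def evaluate(self, data: DataMatrix) -> MetricsReport:
        """Confusion-matrix metrics on a labelled test matrix."""
        pred = self.predict(data)
        cm = ConfusionMatrix.from_labels(pred, data.y, self.ensemble.classes)
        return metrics_from_confusion(cm)

    @property
    def diagnostics(self) -> pd.DataFrame:
        rows = []
        for bc in self.ensemble.classifiers:
            pure = float(np.mean(np.isclose(bc.support.max(axis=1), 1.0)))
            rows.append({
                "classifier": bc.index,
                "subset_size": bc.subset.size,
                "raw_draw_size": len(bc.subset.raw_draw),
                "clusters_retained": bc.n_clusters,
                "pure_cluster_share": pure,
            })
        return pd.DataFrame(rows).set_index("classifier")

    def summary(self) -> str:
        e = self.ensemble
        diag = self.diagnostics
        lines = [
            "Cluster-Based Classifier Ensemble",
            "=" * 41,
            f"base classifiers (K)   {e.n_classifiers:>6d}",
            f"classes (M)            {e.n_classes:>6d}",
            f"features (L)           {len(e.inventory):>6d}",
            f"encoding               {e.encoding:>6s}",
            f"majority class         {e.majority_class}",
            f"seed                   {e.seed}",
            "",
            f"subset size      mean {diag['subset_size'].mean():5.1f}  "
            f"range [{diag['subset_size'].min()}, {diag['subset_size'].max()}]",
            f"clusters kept    mean {diag['clusters_retained'].mean():5.1f}  "
            f"range [{diag['clusters_retained'].min()}, {diag['clusters_retained'].max()}]",
            f"pure-cluster share     {diag['pure_cluster_share'].mean():5.2f}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.ensemble.save(path)

    @classmethod
    def load(cls, path: str | Path) -> "CBCEResults":
        """Rehydrate a fitted result from a model JSON (no training data)."""
        return cls(None, Ensemble.load(path))
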