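"""Sensor-event encoding for segmented activity recognition.

A smart-home installation emits a stream of sensor activations (a cupboard
opened, a toilet flushed, a door passed).  After segmentation, each activity
instance is an ordered sequence of sensor labels together with a ground-truth
activity label.  Instance-based classifiers need fixed-length vectors, so every
instance is projected onto a fixed sensor inventory in one of two ways:

* **numeric** — position *p* holds the number of times sensor *p* fired in the
  segment (an occurrence count), or
* **binary**  — position *p* is 1 iff sensor *p* fired at least once.

Both encodings discard event order; permuting a segment's events leaves the
vector unchanged.  This is deliberate — the downstream classifier treats an
activity as a bag of sensor interactions — but it means datasets whose classes
differ only by ordering cannot be separated after encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorInventory",
    "ActivityInstance",
    "FeatureVector",
    "DataMatrix",
    "DEFAULT_SENSOR_LABELS",
    "default_inventory",
    "encode_numeric",
    "encode_binary",
    "encode_instances",
    "load_events",
    "save_events",
    "load_matrix",
    "save_matrix",
]

Encoding = Literal["numeric", "binary"]

#: The 14-sensor roster of a widely used single-resident smart-apartment
#: deployment (one wireless contact/float sensor per household object), in the
#: fixed vector-layout order used throughout this package.
DEFAULT_SENSOR_LABELS: tuple[str, ...] = (
    "Microwave",
    "Hall-Toilet door",
    "Hall-Bathroom door",
    "Cups cupboard",
    "Fridge",
    "Plates cupboard",
    "Front door",
    "Dishwasher",
    "Toilet Flush",
    "Freezer",
    "Pans Cupboard",
    "Washing machine",
    "Groceries Cupboard",
    "Hall-Bedroom door",
)


class UnknownSensorError(KeyError):
    """A sensor label could not be resolved against the inventory."""


@dataclass(frozen=True)
class SensorInventory:
    """An ordered roster of sensor labels defining the vector layout.

    Vector position follows roster order (0-based internally); labels must be
    unique.  ``L = len(inventory)`` is the feature-space dimension.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("inventory needs at least one sensor")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({s for s in self.labels if list(self.labels).count(s) > 1})
            raise ValueError(f"duplicate sensor labels: {dupes}")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def positions(self) -> dict[str, int]:
        return {label: i for i, label in enumerate(self.labels)}

    def index(self, label: str) -> int:
        try:
            return self.positions[label]
        except KeyError:
            raise UnknownSensorError(label) from None

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.positions


def default_inventory() -> SensorInventory:
    """The bundled 14-sensor smart-apartment inventory."""
    return SensorInventory(DEFAULT_SENSOR_LABELS)


@dataclass(frozen=True)
class ActivityInstance:
    """One segmented activity: an ordered sensor-label sequence plus its label.

    Timestamps, when present, are carried through unchanged; the encodings and
    the classifier never consult them (segmentation is assumed done upstream).
    """

    segment_id: str
    sensors: tuple[str, ...]
    activity: str | None = None
    timestamps: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sensors", tuple(self.sensors))
        if self.timestamps is not None:
            if len(self.timestamps) != len(self.sensors):
                raise ValueError("timestamps must align 1:1 with sensor events")
            object.__setattr__(self, "timestamps", tuple(self.timestamps))


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length non-negative encoding of one instance."""

    values: np.ndarray
    encoding: Encoding
    label: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("feature vector must be 1-D")
        if (v < 0).any():
            raise ValueError("feature values must be non-negative")
        if self.encoding == "binary" and not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("binary encoding admits only 0/1 values")
        if self.encoding == "numeric" and not (v == np.round(v)).all():
            raise ValueError("numeric encoding admits only integer counts")
        object.__setattr__(self, "values", v)
        v.setflags(write=False)


def _resolve(instance: ActivityInstance, inventory: SensorInventory,
             on_unknown: str) -> list[int]:
    pos = inventory.positions
    out = []
    for event_no, label in enumerate(instance.sensors):
        p = pos.get(label)
        if p is None:
            if on_unknown == "ignore":
                continue
            raise UnknownSensorError(
                f"unknown sensor {label!r} at event {event_no} of segment "
                f"{instance.segment_id!r}"
            )
        out.append(p)
    return out


def encode_numeric(instance: ActivityInstance, inventory: SensorInventory,
                   on_unknown: Literal["raise", "ignore"] = "raise") -> FeatureVector:
    """Occurrence-count encoding: position *p* counts sensor *p*'s events.

    The vector sum equals the number of (resolvable) events in the segment.
    Unknown sensor labels raise by default; ``on_unknown="ignore"`` drops them.
    """
    counts = np.zeros(len(inventory))
    for p in _resolve(instance, inventory, on_unknown):
        counts[p] += 1
    return FeatureVector(counts, "numeric", instance.activity)


def encode_binary(instance: ActivityInstance, inventory: SensorInventory,
                  on_unknown: Literal["raise", "ignore"] = "raise") -> FeatureVector:
    """Presence encoding: position *p* is 1 iff sensor *p* fired at all."""
    values = np.zeros(len(inventory))
    for p in _resolve(instance, inventory, on_unknown):
        values[p] = 1.0
    return FeatureVector(values, "binary", instance.activity)


@dataclass
class DataMatrix:
    """N encoded instances sharing one inventory, encoding and class list.

    ``classes`` fixes the class ordering used by support matrices, fused
    supports and tie-breaking; by default it is label first-appearance order.
    """

    X: np.ndarray
    y: np.ndarray
    inventory: SensorInventory
    encoding: Encoding
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (instances x sensors)")
        if self.X.shape[1] != len(self.inventory):
            raise ValueError(
                f"row length {self.X.shape[1]} != inventory size {len(self.inventory)}"
            )
        if len(self.y) != self.X.shape[0]:
            raise ValueError("labels must align 1:1 with rows")
        if not self.classes:
            seen: dict[str, None] = {}
            for label in self.y:
                seen.setdefault(label, None)
            self.classes = tuple(seen)
        else:
            self.classes = tuple(self.classes)
            missing = set(self.y) - set(self.classes)
            if missing:
                raise ValueError(f"row labels not in class list: {sorted(missing)}")
        if len(self.classes) < 1:
            raise ValueError("need at least one class")

    @property
    def n_instances(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_index(self) -> np.ndarray:
        lookup = {c: j for j, c in enumerate(self.classes)}
        return np.array([lookup[label] for label in self.y], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.inventory.labels))
        df["class"] = self.y
        return df


def encode_instances(instances: Sequence[ActivityInstance],
                     inventory: SensorInventory,
                     encoding: Encoding,
                     on_unknown: Literal["raise", "ignore"] = "raise",
                     classes: Sequence[str] | None = None) -> DataMatrix:
    """Encode a batch of labelled instances into a :class:`DataMatrix`."""
    enc = encode_numeric if encoding == "numeric" else encode_binary
    if encoding not in ("numeric", "binary"):
        raise ValueError(f"unknown encoding {encoding!r}")
    vectors = [enc(inst, inventory, on_unknown) for inst in instances]
    labels = [inst.activity for inst in instances]
    if any(label is None for label in labels):
        raise ValueError("all instances must carry an activity label")
    return DataMatrix(
        np.array([v.values for v in vectors]),
        np.array(labels, dtype=object),
        inventory,
        encoding,
        tuple(classes) if classes is not None else (),
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ("segment_id", "sensor", "activity")


def load_events(path: str | Path) -> list[ActivityInstance]:
    """Read an event CSV (one row per sensor event, in occurrence order).

    Required columns: ``segment_id, sensor, activity``; optional ``timestamp``
    (ISO-8601, preserved but unused).  Rows of one segment must agree on the
    activity label, and must be contiguous in event order.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file {path} missing column(s): {missing}")
    instances = []
    seen: set[str] = set()
    for seg_id, group in df.groupby("segment_id", sort=False):
        if seg_id in seen:  # groupby cannot produce this; guard for future edits
            raise ValueError(f"duplicate segment id {seg_id!r}")
        seen.add(seg_id)
        activities = group["activity"].unique()
        if len(activities) != 1:
            raise ValueError(
                f"segment {seg_id!r} carries conflicting activity labels: "
                f"{sorted(activities)}"
            )
        timestamps = (
            tuple(group["timestamp"]) if "timestamp" in df.columns
            and group["timestamp"].notna().all() else None
        )
        instances.append(
            ActivityInstance(str(seg_id), tuple(group["sensor"]),
                             activities[0], timestamps)
        )
    return instances


def save_events(instances: Iterable[ActivityInstance], path: str | Path) -> None:
    rows = []
    for inst in instances:
        for i, sensor in enumerate(inst.sensors):
            row = {"segment_id": inst.segment_id, "sensor": sensor,
                   "activity": inst.activity}
            if inst.timestamps is not None:
                row["timestamp"] = inst.timestamps[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def save_matrix(matrix: DataMatrix, path: str | Path) -> None:
    """Write a matrix as CSV (sensor-label header + ``class`` column) or JSON.

    The JSON form (chosen by a ``.json`` suffix) additionally records the
    inventory, the encoding and the class ordering, and round-trips exactly.
    """
    path = Path(path)
    if path.suffix == ".json":
        doc = {
            "inventory": list(matrix.inventory.labels),
            "encoding": matrix.encoding,
            "classes": list(matrix.classes),
            "rows": [
                {"values": row.tolist(), "class": label}
                for row, label in zip(matrix.X, matrix.y)
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        matrix.to_dataframe().to_csv(path, index=False)


def load_matrix(path: str | Path, encoding: Encoding | None = None,
                classes: Sequence[str] | None = None) -> DataMatrix:
    """Read a matrix written by :func:`save_matrix`.

    For CSV input the encoding is inferred (all-0/1 values ⇒ binary) unless
    given explicitly; JSON input carries its encoding and rejects a
    conflicting ``encoding`` argument.
    """
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text())
        if encoding is not None and encoding != doc["encoding"]:
            raise ValueError(
                f"file encodes {doc['encoding']!r} data but {encoding!r} requested"
            )
        return DataMatrix(
            np.array([r["values"] for r in doc["rows"]], dtype=float),
            np.array([r["class"] for r in doc["rows"]], dtype=object),
            SensorInventory(tuple(doc["inventory"])),
            doc["encoding"],
            tuple(doc.get("classes") or ()),
        )
    df = pd.read_csv(path)
    if "class" not in df.columns:
        raise ValueError(f"matrix file {path} has no 'class' column")
    y = df.pop("class").astype(str).to_numpy(dtype=object)
    X = df.to_numpy(dtype=float)
    if encoding is None:
        encoding = "binary" if np.isin(X, (0.0, 1.0)).all() else "numeric"
    return DataMatrix(X, y, SensorInventory(tuple(df.columns)), encoding,
                      tuple(classes) if classes is not None else ())
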