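"""Synthetic smart-home activity streams.

Emulates the structure of single-resident ambient-sensor datasets: a fixed
inventory of object sensors (doors, cupboards, appliances), a handful of
activity classes with strongly imbalanced frequencies, and per-activity
sensor signatures that overlap for confusable pairs (meal preparation
activities share the fridge and food cupboards).

Each activity class is an :class:`ActivityTemplate`: a per-sensor activation
probability, a per-sensor geometric occurrence-count parameter (geometric,
because an activated object is typically touched once or twice but
occasionally many times — the fridge during cooking), and an expected
frequency weight.  An instance draws its template by weight, activates
sensors by probability (redrawing when the draw comes up empty, since a
segmented activity always contains at least one event),
draws a count per activated sensor, and emits the events in random order —
order carries no signal by construction, matching what the downstream
encodings can see.  Spurious activations are injected at a configurable
noise rate.

What this generator does **not** emulate: realistic daily timing, interleaved
or concurrent activities, sensor hardware failures, or within-class modes
(e.g. two genuinely different ways of cooking).  Results on this data bound
what the classifier can do under its own assumptions, not on real homes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .encoding import (
    ActivityInstance,
    DataMatrix,
    SensorInventory,
    default_inventory,
    encode_instances,
)

__all__ = [
    "ActivityTemplate",
    "SyntheticConfig",
    "generate",
    "generate_matrix",
    "default_paperlike_config",
    "synthetic_config",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class ActivityTemplate:
    """One activity class's generative profile."""

    label: str
    activation_probs: np.ndarray  # length L, in [0, 1]
    count_p: np.ndarray           # length L, geometric parameter in (0, 1]
    weight: float                 # expected relative frequency

    def __post_init__(self) -> None:
        probs = np.asarray(self.activation_probs, dtype=float)
        count_p = np.asarray(self.count_p, dtype=float)
        if probs.ndim != 1 or probs.shape != count_p.shape:
            raise ValueError("activation_probs and count_p must be 1-D and aligned")
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("activation probabilities must lie in [0, 1]")
        if (probs > 0).sum() == 0:
            raise ValueError(f"template {self.label!r} activates no sensor")
        if ((count_p <= 0) | (count_p > 1)).any():
            raise ValueError("geometric count parameters must lie in (0, 1]")
        if self.weight <= 0:
            raise ValueError("template weight must be positive")
        object.__setattr__(self, "activation_probs", probs)
        object.__setattr__(self, "count_p", count_p)
        probs.setflags(write=False)
        count_p.setflags(write=False)


@dataclass(frozen=True)
class SyntheticConfig:
    """A full dataset recipe: inventory, templates, size, noise."""

    inventory: SensorInventory
    templates: tuple[ActivityTemplate, ...]
    n_instances: int
    noise_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "templates", tuple(self.templates))
        if self.n_instances < 1:
            raise ValueError("need at least one instance")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise rate must lie in [0, 1]")
        L = len(self.inventory)
        for t in self.templates:
            if len(t.activation_probs) != L:
                raise ValueError(
                    f"template {t.label!r} has {len(t.activation_probs)} sensor "
                    f"slots, inventory has {L}"
                )
        labels = [t.label for t in self.templates]
        if len(set(labels)) != len(labels):
            raise ValueError("template labels must be unique")

    @property
    def weights(self) -> np.ndarray:
        w = np.array([t.weight for t in self.templates], dtype=float)
        return w / w.sum()

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.templates)


def generate(config: SyntheticConfig, seed: int | None = None) -> list[ActivityInstance]:
    """Draw ``config.n_instances`` labelled activity segments."""
    rng = np.random.default_rng(seed)
    L = len(config.inventory)
    labels = config.inventory.labels
    weights = config.weights
    instances = []
    for i in range(config.n_instances):
        t = config.templates[int(rng.choice(len(config.templates), p=weights))]
        # redraw until some sensor fires: a segmented activity always has at
        # least one event, and conditioning keeps relative rates undistorted
        active = rng.random(L) < t.activation_probs
        for _ in range(1000):
            if active.any():
                break
            active = rng.random(L) < t.activation_probs
        else:
            active[int(np.argmax(t.activation_probs))] = True
        counts = np.zeros(L, dtype=int)
        counts[active] = rng.geometric(t.count_p[active])
        if config.noise_rate > 0:
            spurious = (~active) & (rng.random(L) < config.noise_rate)
            counts[spurious] = 1
        events = [labels[p] for p in range(L) for _ in range(counts[p])]
        rng.shuffle(events)
        instances.append(ActivityInstance(f"seg{i:05d}", tuple(events), t.label))
    return instances


def generate_matrix(config: SyntheticConfig, encoding: str,
                    seed: int | None = None) -> DataMatrix:
    """Generate and encode in one step, with the template class ordering."""
    return encode_instances(generate(config, seed), config.inventory, encoding,
                            classes=config.classes)


# ---------------------------------------------------------------------------
# Ready-made configurations
# ---------------------------------------------------------------------------

# Per-activity profiles over the default 14-sensor inventory.  Frequencies
# follow the strongly imbalanced class counts typical of annotated ADL data
# (toileting dominates; cooking dinner is rare).  The two meal-preparation
# activities share the Fridge / Plates cupboard / Groceries Cupboard
# signature and differ through Freezer, Pans Cupboard and Microwave, making
# them the designated confusable pair.
_PAPERLIKE_PROFILES: dict[str, tuple[int, dict[str, tuple[float, float]]]] = {
    # label: (frequency weight, {sensor: (activation prob, geometric p)})
    "Leave house": (34, {"Front door": (0.95, 0.6)}),
    "Use toilet": (112, {"Hall-Bathroom door": (0.9, 0.5),
                         "Toilet Flush": (0.95, 0.6),
                         "Hall-Toilet door": (0.35, 0.7)}),
    "Take shower": (23, {"Hall-Bathroom door": (0.95, 0.5),
                         "Toilet Flush": (0.3, 0.8)}),
    "Go to bed": (24, {"Hall-Bedroom door": (0.95, 0.5)}),
    "Prepare breakfast": (20, {"Fridge": (0.9, 0.45),
                               "Plates cupboard": (0.8, 0.6),
                               "Groceries Cupboard": (0.7, 0.55),
                               "Cups cupboard": (0.3, 0.7)}),
    "Prepare dinner": (10, {"Fridge": (0.9, 0.35),
                            "Plates cupboard": (0.7, 0.55),
                            "Groceries Cupboard": (0.55, 0.5),
                            "Freezer": (0.7, 0.6),
                            "Pans Cupboard": (0.8, 0.6),
                            "Microwave": (0.4, 0.7)}),
    "Get drink": (22, {"Fridge": (0.85, 0.6),
                       "Cups cupboard": (0.9, 0.65)}),
}


def default_paperlike_config(n_instances: int = 245,
                             noise_rate: float = 0.02) -> SyntheticConfig:
    """A seven-activity, 14-sensor recipe mirroring a real annotated ADL set.

    Class weights are proportional to the counts 34 : 112 : 23 : 24 : 20 :
    10 : 22 (leave house / use toilet / take shower / go to bed / prepare
    breakfast / prepare dinner / get drink); the default size, 245 instances,
    matches the scale such corpora actually have.
    """
    inventory = default_inventory()
    L = len(inventory)
    templates = []
    for label, (weight, sensors) in _PAPERLIKE_PROFILES.items():
        probs = np.zeros(L)
        count_p = np.ones(L)
        for sensor, (p_act, p_count) in sensors.items():
            pos = inventory.index(sensor)
            probs[pos] = p_act
            count_p[pos] = p_count
        templates.append(ActivityTemplate(label, probs, count_p, float(weight)))
    return SyntheticConfig(inventory, tuple(templates), n_instances, noise_rate)


def synthetic_config(n_classes: int = 7,
                     sensors_per_class: int = 2,
                     n_instances: int = 300,
                     overlap: float = 0.0,
                     noise_rate: float = 0.0,
                     activation_prob: float = 0.9,
                     count_p: float = 0.5,
                     weights: tuple[float, ...] | None = None,
                     confusable_pairs: tuple[tuple[int, int], ...] | None = None,
                     ) -> SyntheticConfig:
    """Parametric recipe with controllable class overlap.

    Each class owns ``sensors_per_class`` private sensors from a generic
    inventory of ``n_classes * sensors_per_class`` sensors, so ``overlap=0``
    gives disjoint per-class signatures.  For each confusable pair (a, b) —
    by default the last two classes — a fraction ``overlap`` of b's sensors
    is replaced by a's sensors; ``overlap=1`` makes the pair's activation
    profiles identical (their instances statistically exchangeable).
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    L = n_classes * sensors_per_class
    inventory = SensorInventory(tuple(f"sensor-{i + 1:02d}" for i in range(L)))
    if weights is None:
        weights = tuple(1.0 for _ in range(n_classes))
    if confusable_pairs is None:
        confusable_pairs = ((n_classes - 2, n_classes - 1),) if n_classes >= 2 else ()
    sensor_sets = [list(range(c * sensors_per_class, (c + 1) * sensors_per_class))
                   for c in range(n_classes)]
    for a, b in confusable_pairs:
        n_shared = int(round(overlap * sensors_per_class))
        sensor_sets[b][:n_shared] = sensor_sets[a][:n_shared]
    templates = []
    for c in range(n_classes):
        probs = np.zeros(L)
        probs[sorted(set(sensor_sets[c]))] = activation_prob
        templates.append(ActivityTemplate(
            f"activity-{c + 1}", probs, np.full(L, count_p), float(weights[c]),
        ))
    return SyntheticConfig(inventory, tuple(templates), n_instances, noise_rate)


# ---------------------------------------------------------------------------
# Config (de)serialisation
# ---------------------------------------------------------------------------

def _config_to_dict(config: SyntheticConfig) -> dict:
    return {
        "inventory": list(config.inventory.labels),
        "n_instances": config.n_instances,
        "noise_rate": config.noise_rate,
        "templates": [
            {
                "label": t.label,
                "weight": t.weight,
                "activation_probs": t.activation_probs.tolist(),
                "count_p": t.count_p.tolist(),
            }
            for t in config.templates
        ],
    }


def _config_from_dict(doc: dict) -> SyntheticConfig:
    inventory = SensorInventory(tuple(doc["inventory"]))
    templates = tuple(
        ActivityTemplate(
            t["label"],
            np.array(t["activation_probs"], dtype=float),
            np.array(t["count_p"], dtype=float),
            float(t["weight"]),
        )
        for t in doc["templates"]
    )
    return SyntheticConfig(inventory, templates, int(doc["n_instances"]),
                           float(doc.get("noise_rate", 0.0)))


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    path = Path(path)
    doc = _config_to_dict(config)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))


def load_config(path: str | Path) -> SyntheticConfig:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return _config_from_dict(doc)
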