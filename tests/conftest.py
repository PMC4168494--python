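import numpy as np
import pytest
from hypothesis import settings

from cbce.encoding import ActivityInstance, DataMatrix, default_inventory
from cbce.synthetic import default_paperlike_config, synthetic_config

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def inventory():
    return default_inventory()


@pytest.fixture
def toileting_instance():
    """Door, three flushes, door — the canonical walk-through sequence."""
    return ActivityInstance(
        "seg-toilet",
        ("Hall-Bathroom door", "Toilet Flush", "Toilet Flush", "Toilet Flush",
         "Hall-Bathroom door"),
        "Use toilet",
    )


@pytest.fixture
def paperlike_config():
    return default_paperlike_config()


@pytest.fixture
def disjoint_config():
    """Seven classes with fully disjoint two-sensor signatures, no noise."""
    return synthetic_config(overlap=0.0, noise_rate=0.0, n_instances=300)


@pytest.fixture
def separable_matrix(inventory):
    """Two far-apart numeric blobs, trivially separable."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 0.3, size=(20, 14)).clip(0).round()
    b = (10.0 + rng.normal(0.0, 0.3, size=(20, 14))).round()
    X = np.vstack([a, b])
    y = np.array(["low"] * 20 + ["high"] * 20, dtype=object)
    return DataMatrix(X, y, inventory, "numeric")
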