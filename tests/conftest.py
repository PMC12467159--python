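import numpy as np
import pytest

from octatex.io import DatasetManifest, ManifestRecord
from octatex.features import LAYERS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """Moderate-contrast 24x24 grey image, 8-bit scale."""
    return rng.integers(0, 256, size=(24, 24)).astype(float)


def make_manifest(n_per_label: dict[str, int], layers=LAYERS) -> DatasetManifest:
    """Build a manifest with synthetic paths, one image per (eye, layer)."""
    records = []
    for label, n in n_per_label.items():
        for i in range(n):
            eye = f"{label}_{i:03d}"
            for layer in layers:
                records.append(ManifestRecord(eye, layer, label, f"{eye}_{layer}.png"))
    return DatasetManifest(records=records)


@pytest.fixture
def four_layer_manifest():
    return make_manifest({"healthy": 3, "wet_amd": 3})
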