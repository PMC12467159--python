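"""Per-eye feature assembly.

Each eye contributes one row: the concatenation of its per-layer descriptor
histograms in the canonical layer order (superficial, deep, outer,
choriocapillaris). Rows are keyed by eye id so manifest shuffling cannot
change row/label alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from octatex.io import TASK_CLASSES, DatasetManifest, load_images
from octatex.lbp import CircularNeighbourhoodConfig, dense_code_map, histogram
from octatex.brief import BriefConfig, dense_brief_map

LAYERS = ("superficial", "deep", "outer", "choriocapillaris")

DESCRIPTORS = ("lbp_riu2", "lbp", "brief")


@dataclass(frozen=True)
class FeatureMatrix:
    """N x F matrix of per-eye feature vectors with aligned labels."""

    D: np.ndarray
    eye_ids: tuple[str, ...]
    labels: np.ndarray
    layers: tuple[str, ...]
    fingerprint: str = ""

    def __post_init__(self):
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2:
            raise ValueError("D must be 2-D")
        if not np.all(np.isfinite(D)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.eye_ids) != D.shape[0] or len(self.labels) != D.shape[0]:
            raise ValueError("eye_ids/labels length mismatch with D")
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    @property
    def n_eyes(self) -> int:
        return self.D.shape[0]

    @property
    def n_features(self) -> int:
        return self.D.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.D, columns=[f"f{i}" for i in range(self.n_features)])
        df.insert(0, "eye_id", list(self.eye_ids))
        df.insert(1, "label", self.labels)
        df.to_csv(path, index=False)


def canonical_layers(layer_set) -> tuple[str, ...]:
    """Order an arbitrary layer collection canonically; reject unknowns."""
    layers = tuple(l for l in LAYERS if l in set(layer_set))
    unknown = set(layer_set) - set(LAYERS)
    if unknown:
        raise ValueError(f"unknown layers {sorted(unknown)}")
    if not layers:
        raise ValueError("empty layer set")
    return layers


def enumerate_layer_combinations() -> list[tuple[str, ...]]:
    """All 15 layer combinations: 4 singles, 6 pairs, 4 triples, all four."""
    out: list[tuple[str, ...]] = []
    for size in (1, 2, 3, 4):
        out.extend(combinations(LAYERS, size))
    return out


def _image_histogram(image: np.ndarray, descriptor: str, params) -> np.ndarray:
    if descriptor in ("lbp", "lbp_riu2"):
        if not isinstance(params, CircularNeighbourhoodConfig):
            raise TypeError("LBP descriptors need a CircularNeighbourhoodConfig")
        variant = "riu2" if descriptor == "lbp_riu2" else "generic"
        return histogram(dense_code_map(image, params, variant), normalize=True).bins
    if descriptor == "brief":
        if not isinstance(params, BriefConfig):
            raise TypeError("BRIEF descriptor needs a BriefConfig")
        _, hist = dense_brief_map(image, params, normalize=True)
        return hist.bins
    raise ValueError(f"unknown descriptor {descriptor!r}; choose from {DESCRIPTORS}")


def _fingerprint(descriptor: str, params, layers: tuple[str, ...]) -> str:
    if isinstance(params, CircularNeighbourhoodConfig):
        ptag = f"p{params.p}_r{params.r:g}"
    elif isinstance(params, BriefConfig):
        ptag = f"S{params.S}_n{params.n}_seed{params.seed}"
    else:
        ptag = repr(params)
    return f"{descriptor}_{ptag}_" + "+".join(layers)


def extract_features(
    manifest: DatasetManifest,
    descriptor: str,
    params,
    layer_set,
    task: str | None = None,
    root: str | Path | None = None,
    images: dict[tuple[str, str], np.ndarray] | None = None,
) -> FeatureMatrix:
    """Build the per-eye feature matrix for one descriptor and layer set.

    ``task`` (default: the manifest's ``classification_task``) maps condition
    labels to the binary target; eyes whose label does not participate in the
    task are dropped. Images may be supplied pre-loaded via ``images`` keyed
    by ``(eye_id, layer)``, otherwise they are read from disk.

    Raises a ``ValueError`` naming the eye if a requested layer is missing.
    """
    task = task or manifest.classification_task
    if task is None:
        raise ValueError("no classification task given")
    class_map = TASK_CLASSES[task]
    layers = canonical_layers(layer_set)

    if images is None:
        loaded = load_images(manifest, root=root)
        images = {(im.eye_id, im.layer): im.pixels for im in loaded}

    rows, eye_ids, labels = [], [], []
    for eye in manifest.eyes:
        label = manifest.label_of(eye)
        if label not in class_map:
            continue
        parts = []
        for layer in layers:
            key = (eye, layer)
            if key not in images:
                raise ValueError(f"eye {eye!r} is missing requested layer {layer!r}")
            parts.append(_image_histogram(images[key], descriptor, params))
        rows.append(np.concatenate(parts))
        eye_ids.append(eye)
        labels.append(class_map[label])

    if not rows:
        raise ValueError(f"no eyes with labels participating in task {task!r}")
    return FeatureMatrix(
        D=np.vstack(rows),
        eye_ids=tuple(eye_ids),
        labels=np.asarray(labels),
        layers=layers,
        fingerprint=_fingerprint(descriptor, params, layers),
    )
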