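"""Seeded synthetic greyscale vascular-texture datasets.

Two classes are generated with controllable separability:

* class A ("healthy-like"): filamentous curvilinear bright structures —
  random smooth spline curves stroked at width 1-3 px and blurred — on a
  dark background, plus optional multiplicative speckle;
* class B ("CNV-like"): the same filament base plus bright irregular blob
  clusters and local dropout patches, at a rate set by ``lesion_density``.

At ``lesion_density == 0`` the two classes are statistically identical, so
any pipeline evaluated on such a dataset must score at chance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.interpolate import make_interp_spline
from scipy.ndimage import gaussian_filter, grey_dilation

from octatex.io import DatasetManifest, ManifestRecord, write_manifest
from octatex.features import LAYERS


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic two-class dataset."""

    n_eyes: int = 30  # per class
    image_size: tuple[int, int] = (320, 320)
    layers: tuple[str, ...] = LAYERS
    lesion_density: float = 1.0
    tortuosity: float = 1.0
    noise_std: float = 0.0
    seed: int = 42
    n_curves: int = 25

    def __post_init__(self):
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if not 0.0 <= self.lesion_density <= 1.0:
            raise ValueError("lesion_density must be in [0, 1]")
        for v in (self.tortuosity, self.noise_std):
            if not np.isfinite(v) or v < 0:
                raise ValueError("parameters must be finite and >= 0")
        unknown = set(self.layers) - set(LAYERS)
        if unknown:
            raise ValueError(f"unknown layers {sorted(unknown)}")


def _random_curve(rng: np.random.Generator, shape: tuple[int, int], tortuosity: float) -> np.ndarray:
    """Points along a random smooth curve spanning the image."""
    h, w = shape
    n_ctrl = max(4, int(3 + 3 * tortuosity))
    t = np.linspace(0, 1, n_ctrl)
    ctrl = np.column_stack([rng.uniform(0, h, n_ctrl), rng.uniform(0, w, n_ctrl)])
    spline = make_interp_spline(t, ctrl, k=3)
    dense = spline(np.linspace(0, 1, 40 * n_ctrl))
    return dense


def _stroke(canvas: np.ndarray, points: np.ndarray, width: int, value: float) -> None:
    h, w = canvas.shape
    pts = np.round(points).astype(int)
    keep = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[keep]
    mask = np.zeros_like(canvas, dtype=bool)
    mask[pts[:, 0], pts[:, 1]] = True
    if width > 1:
        mask = grey_dilation(mask.astype(np.uint8), size=(width, width)).astype(bool)
    canvas[mask] = np.maximum(canvas[mask], value)


def _filament_base(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    img = np.zeros(spec.image_size, dtype=float)
    for _ in range(spec.n_curves):
        pts = _random_curve(rng, spec.image_size, spec.tortuosity)
        width = int(rng.integers(1, 4))
        value = rng.uniform(150, 255)
        _stroke(img, pts, width, value)
    img = gaussian_filter(img, sigma=0.8)
    img += 12.0  # dim background so dropout is visible
    return img


def _add_lesions(img: np.ndarray, rng: np.random.Generator, density: float) -> np.ndarray:
    """Bright irregular blob clusters plus dark dropout patches."""
    h, w = img.shape
    out = img.copy()
    area_scale = (h * w) / (320 * 320)
    n_blobs = rng.binomial(max(1, int(30 * area_scale)), density)
    n_drop = rng.binomial(max(1, int(12 * area_scale)), density)
    rr, cc = np.mgrid[0:h, 0:w]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        # cluster of 2-4 overlapping disks -> irregular blob
        for _ in range(int(rng.integers(2, 5))):
            dy, dx = rng.normal(0, 4, size=2)
            rad = rng.uniform(3, 9)
            mask = (rr - cy - dy) ** 2 + (cc - cx - dx) ** 2 <= rad**2
            out[mask] = np.maximum(out[mask], rng.uniform(200, 255))
    for _ in range(n_drop):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        rad = rng.uniform(5, 14)
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= rad**2
        out[mask] = out[mask] * 0.08
    return out


def _speckle(img: np.ndarray, rng: np.random.Generator, noise_std: float) -> np.ndarray:
    if noise_std <= 0:
        return np.clip(img, 0, 255)
    noisy = img + (img / 255.0) * rng.normal(0.0, noise_std, size=img.shape)
    return np.clip(noisy, 0, 255)


def generate_images(spec: SyntheticSpec) -> tuple[dict[tuple[str, str], np.ndarray], dict[str, str]]:
    """In-memory dataset: image per (eye_id, layer) plus eye labels.

    Class A eyes are labelled ``healthy``, class B eyes ``wet_amd``. All
    randomness flows from one generator seeded by ``spec.seed``, so the
    result is reproducible bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    images: dict[tuple[str, str], np.ndarray] = {}
    labels: dict[str, str] = {}
    for cls, label in (("A", "healthy"), ("B", "wet_amd")):
        for i in range(spec.n_eyes):
            eye = f"{label}_{i:03d}"
            labels[eye] = label
            for layer in spec.layers:
                base = _filament_base(rng, spec)
                if cls == "B":
                    base = _add_lesions(base, rng, spec.lesion_density)
                img = _speckle(base, rng, spec.noise_std)
                images[(eye, layer)] = np.round(img).astype(np.uint8).astype(float)
    return images, labels


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> DatasetManifest:
    """Write PNG images and a manifest CSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, labels = generate_images(spec)
    records = []
    for (eye, layer), img in images.items():
        rel = f"{eye}_{layer}.png"
        Image.fromarray(img.astype(np.uint8), mode="L").save(out_dir / rel)
        records.append(ManifestRecord(eye_id=eye, layer=layer, label=labels[eye], path=rel))
    manifest = DatasetManifest(records=records)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest


# ---------------------------------------------------------------------------
# tiny hand-checkable fixtures

def _constant(size: int = 8, value: float = 100.0):
    img = np.full((size, size), value)
    expected = {"riu2_p8_r1": np.full((size - 2, size - 2), 8, dtype=np.int64)}
    return img, expected


def _checkerboard(size: int = 8):
    # period-1 board: parity-0 pixels are 0, parity-1 pixels are 255.
    # With p=8, r=1 every axis and (interpolated) diagonal sample around a
    # dark centre exceeds it -> code 255 -> label 8; around a bright centre
    # every sample falls below it -> code 0 -> label 0.
    rr, cc = np.mgrid[0:size, 0:size]
    img = ((rr + cc) % 2) * 255.0
    parity = (rr + cc)[1:-1, 1:-1] % 2
    expected = {"riu2_p8_r1": np.where(parity == 1, 0, 8).astype(np.int64)}
    return img, expected


def _step_edge(size: int = 8, low: float = 0.0, high: float = 200.0):
    img = np.full((size, size), low)
    img[:, size // 2 :] = high
    return img, {}


def _diagonal(size: int = 8):
    img = np.zeros((size, size))
    np.fill_diagonal(img, 255.0)
    return img, {}


_FIXTURES = {
    "constant": _constant,
    "checkerboard": _checkerboard,
    "step_edge": _step_edge,
    "diagonal": _diagonal,
}


def tiny_fixture(name: str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Small deterministic image plus precomputed expected code maps."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}") from None
    return factory()
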