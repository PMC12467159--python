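"""Image and manifest input/output.

Greyscale layer images are read from PNG/TIFF into float64 matrices on the
8-bit scale; a CSV manifest (header ``eye_id,layer,label,path``) ties each
image to an eye, an anatomical layer and a condition label.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

LAYERS = ("superficial", "deep", "outer", "choriocapillaris")
LABELS = ("healthy", "dry_amd", "wet_amd", "secondary_cnv")
TASKS = ("healthy_vs_wet", "dry_vs_wet", "cnv_vs_noncnv")

#: label -> binary class per task; labels absent from the mapping are excluded
TASK_CLASSES = {
    "healthy_vs_wet": {"healthy": 0, "wet_amd": 1},
    "dry_vs_wet": {"dry_amd": 0, "wet_amd": 1},
    "cnv_vs_noncnv": {"dry_amd": 0, "wet_amd": 1, "secondary_cnv": 1},
}

# ITU-R 601 luminance weights for colour -> grey conversion
_LUMA = np.array([0.299, 0.587, 0.114])


class ManifestError(ValueError):
    """Raised on malformed or inconsistent manifests."""


@dataclass(frozen=True)
class OctaImage:
    """A single greyscale layer image with its provenance metadata."""

    pixels: np.ndarray
    eye_id: str = ""
    layer: str = ""
    label: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"pixels must be a 2-D matrix with >=2 rows/cols, got shape {px.shape}")
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("grey levels must be finite and non-negative")
        object.__setattr__(self, "pixels", px)
        if self.layer and self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.label and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class ManifestRecord:
    eye_id: str
    layer: str
    label: str
    path: str


@dataclass
class DatasetManifest:
    """Validated list of (eye, layer, label, path) records."""

    records: list[ManifestRecord] = field(default_factory=list)
    classification_task: str | None = None

    def __post_init__(self):
        if self.classification_task is not None and self.classification_task not in TASKS:
            raise ManifestError(f"unknown task {self.classification_task!r}")
        seen: dict[tuple[str, str], str] = {}
        eye_labels: dict[str, str] = {}
        for rec in self.records:
            if rec.layer not in LAYERS:
                raise ManifestError(f"unknown layer {rec.layer!r} for eye {rec.eye_id!r}")
            if rec.label not in LABELS:
                raise ManifestError(f"unknown label {rec.label!r} for eye {rec.eye_id!r}")
            key = (rec.eye_id, rec.layer)
            if key in seen:
                raise ManifestError(f"duplicate (eye_id, layer) = {key}")
            seen[key] = rec.path
            prev = eye_labels.setdefault(rec.eye_id, rec.label)
            if prev != rec.label:
                raise ManifestError(f"inconsistent labels for eye {rec.eye_id!r}: {prev} vs {rec.label}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def eyes(self) -> list[str]:
        """Eye ids in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.eye_id not in out:
                out.append(rec.eye_id)
        return out

    def label_of(self, eye_id: str) -> str:
        for rec in self.records:
            if rec.eye_id == eye_id:
                return rec.label
        raise KeyError(eye_id)

    def record_for(self, eye_id: str, layer: str) -> ManifestRecord | None:
        for rec in self.records:
            if rec.eye_id == eye_id and rec.layer == layer:
                return rec
        return None

    def counts(self) -> dict[tuple[str, str], int]:
        """Record counts per (layer, label)."""
        out: dict[tuple[str, str], int] = {}
        for rec in self.records:
            key = (rec.layer, rec.label)
            out[key] = out.get(key, 0) + 1
        return out


def read_image(path: str | Path, eye_id: str = "", layer: str = "", label: str = "") -> OctaImage:
    """Read a PNG/TIFF image into an :class:`OctaImage`.

    Colour inputs are converted to luminance (ITU-R 601); values stay on the
    stored 8-bit (or 16-bit) scale.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im, dtype=float)
    except FileNotFoundError:
        raise
    except OSError as exc:
        raise OSError(f"cannot decode image {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2 or arr.size == 0 or min(arr.shape) < 2:
        raise ValueError(f"image {path} has unusable shape {arr.shape}")
    return OctaImage(pixels=arr, eye_id=eye_id, layer=layer, label=label)


def load_manifest(path: str | Path, classification_task: str | None = None) -> DatasetManifest:
    """Load and validate a manifest CSV with header ``eye_id,layer,label,path``."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = ["eye_id", "layer", "label", "path"]
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != expected:
            raise ManifestError(f"manifest header must be exactly {','.join(expected)}, got {reader.fieldnames}")
        records = [
            ManifestRecord(row["eye_id"].strip(), row["layer"].strip(), row["label"].strip(), row["path"].strip())
            for row in reader
        ]
    return DatasetManifest(records=records, classification_task=classification_task)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest CSV; inverse of :func:`load_manifest`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["eye_id", "layer", "label", "path"])
        for rec in manifest.records:
            writer.writerow([rec.eye_id, rec.layer, rec.label, rec.path])


def load_images(manifest: DatasetManifest, root: str | Path | None = None) -> list[OctaImage]:
    """Read every image referenced by ``manifest``; paths resolved against ``root``."""
    root = Path(root) if root is not None else None
    out = []
    for rec in manifest.records:
        p = Path(rec.path)
        if root is not None and not p.is_absolute():
            p = root / p
        out.append(read_image(p, eye_id=rec.eye_id, layer=rec.layer, label=rec.label))
    return out
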