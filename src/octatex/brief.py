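"""Dense BRIEF texture coding with a noise-adaptive threshold.

An ``n``-bit code is produced for every pixel whose ``S x S`` patch fits in
the image, by comparing the grey levels of ``n`` fixed, randomly drawn pixel
pairs inside the patch: bit ``i-1`` is set when ``P(X_i) - P(Y_i)`` exceeds
the threshold. The threshold is three times the image noise standard
deviation, estimated from the residual of a Gaussian blur.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from octatex.lbp import TextureHistogram

#: Gaussian blur used by the noise estimator (sigma in pixels, kernel truncation)
BLUR_SIGMA = 1.0
BLUR_TRUNCATE = 4.0


@dataclass(frozen=True)
class BriefConfig:
    """Sampling pattern: ``n`` pixel pairs inside an ``S x S`` patch.

    One pattern is shared by every patch of every image in a run, so
    histogram bins stay commensurable across images.
    """

    S: int
    n: int
    pairs: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    seed: int

    def __post_init__(self):
        if self.S < 2 or self.n < 1:
            raise ValueError("require S >= 2 and n >= 1")
        if len(self.pairs) != self.n:
            raise ValueError(f"expected {self.n} pairs, got {len(self.pairs)}")
        for x, y in self.pairs:
            for coord in (x, y):
                if not (0 <= coord[0] < self.S and 0 <= coord[1] < self.S):
                    raise ValueError(f"pair coordinate {coord} outside [0, {self.S})^2")
            if x == y:
                raise ValueError("self-pair X_i == Y_i not allowed")

    def to_json(self, path: str | Path) -> None:
        payload = {"S": self.S, "n": self.n, "seed": self.seed,
                   "pairs": [[list(x), list(y)] for x, y in self.pairs]}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BriefConfig":
        payload = json.loads(Path(path).read_text())
        pairs = tuple((tuple(x), tuple(y)) for x, y in payload["pairs"])
        return cls(S=payload["S"], n=payload["n"], pairs=pairs, seed=payload["seed"])


@dataclass(frozen=True)
class NoiseEstimate:
    """Noise standard deviation and derived code threshold (``3 * sigma``)."""

    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def threshold(self) -> float:
        return 3.0 * self.sigma


def make_sampling_pattern(S: int, n: int, seed: int = 42) -> BriefConfig:
    """Draw ``n`` i.i.d. uniform pixel pairs over the ``S x S`` grid.

    Degenerate pairs (``X_i == Y_i``) are redrawn; deterministic given ``seed``.
    """
    if S < 2 or n < 1:
        raise ValueError("require S >= 2 and n >= 1")
    rng = np.random.default_rng(seed)
    pairs = []
    while len(pairs) < n:
        x = tuple(int(v) for v in rng.integers(0, S, size=2))
        y = tuple(int(v) for v in rng.integers(0, S, size=2))
        if x != y:
            pairs.append((x, y))
    return BriefConfig(S=S, n=n, pairs=tuple(pairs), seed=seed)


def estimate_noise_sigma(image: np.ndarray) -> NoiseEstimate:
    """Estimate noise std as the std of ``image - gaussian_blur(image)``."""
    image = np.asarray(image, dtype=float)
    residual = image - gaussian_filter(image, sigma=BLUR_SIGMA, truncate=BLUR_TRUNCATE)
    return NoiseEstimate(sigma=float(residual.std()))


def brief_code(patch: np.ndarray, config: BriefConfig, threshold: float) -> int:
    """Code one ``S x S`` patch: bit ``i-1`` set iff ``P(X_i) - P(Y_i) > threshold``."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (config.S, config.S):
        raise ValueError(f"patch must be {config.S}x{config.S}, got {patch.shape}")
    code = 0
    for i, (x, y) in enumerate(config.pairs):
        if patch[x] - patch[y] > threshold:
            code |= 1 << i
    return code


def dense_brief_map(
    image: np.ndarray, config: BriefConfig, threshold: float | None = None, normalize: bool = True
) -> tuple[np.ndarray, TextureHistogram]:
    """Code every pixel whose patch fits inside ``image`` and histogram the codes.

    The anchor pixel sits at offset ``floor((S - 1) / 2)`` inside its patch.
    When ``threshold`` is None it is taken as ``3 * sigma`` from
    :func:`estimate_noise_sigma` on this image.
    """
    image = np.asarray(image, dtype=float)
    S = config.S
    h, w = image.shape
    if h < S or w < S:
        raise ValueError(f"image {image.shape} smaller than patch size {S}")
    if threshold is None:
        threshold = estimate_noise_sigma(image).threshold
    off = (S - 1) // 2
    oh, ow = h - S + 1, w - S + 1  # number of valid patch positions per axis
    codes = np.zeros((oh, ow), dtype=np.int64)
    for i, ((xr, xc), (yr, yc)) in enumerate(config.pairs):
        diff = image[xr : xr + oh, xc : xc + ow] - image[yr : yr + oh, yc : yc + ow]
        codes |= (diff > threshold).astype(np.int64) << i
    counts = np.bincount(codes.ravel(), minlength=2 ** config.n).astype(float)
    if normalize and counts.sum() > 0:
        counts = counts / counts.sum()
    tag = f"brief_S{config.S}_n{config.n}_seed{config.seed}"
    hist = TextureHistogram(bins=counts, descriptor=tag, normalized=normalize)
    # anchor position: code[r, c] describes the patch whose anchor pixel is
    # image[r + off, c + off]
    return codes, hist
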