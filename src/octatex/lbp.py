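"""Dense local binary pattern coding with circular sampling.

Two variants are provided: the *generic* code, the base-2 weighted sum of
thresholded differences between a centre pixel and ``p`` neighbours sampled
on a circle of radius ``r``, and the rotation-invariant-uniform (*riu2*)
code, which keys patterns with at most two circular bit transitions by their
bit count and pools all remaining patterns into a single label ``p + 1``.

Coding is applied densely to every interior pixel (a margin of ``ceil(r)``
is excluded so no sample ever leaves the image) and summarised as a
fixed-length histogram per image: ``2**p`` bins for the generic variant,
``p + 2`` bins for riu2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: samples closer than this to a grid point bypass interpolation
_GRID_EPS = 1e-9


@dataclass(frozen=True)
class CircularNeighbourhoodConfig:
    """Circular sampling geometry: ``p`` points on a circle of radius ``r``.

    The first sample ``g0`` sits exactly one radius to the right of the
    centre; sample ``n`` is at row/col offset ``(-r*sin(2*pi*n/p),
    r*cos(2*pi*n/p))``, with off-grid positions bilinearly interpolated.
    """

    p: int = 8
    r: float = 1.0

    def __post_init__(self):
        if self.p <= 1:
            raise ValueError("p must be > 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")

    @property
    def margin(self) -> int:
        return int(math.ceil(self.r))

    def offsets(self) -> np.ndarray:
        """(p, 2) array of (row, col) offsets from the centre pixel."""
        n = np.arange(self.p)
        theta = 2.0 * np.pi * n / self.p
        return np.stack([-self.r * np.sin(theta), self.r * np.cos(theta)], axis=1)


@dataclass(frozen=True)
class LbpCodeImage:
    """Per-pixel codes for the interior of a source image."""

    codes: np.ndarray
    variant: str  # "generic" | "riu2"
    config: CircularNeighbourhoodConfig

    def __post_init__(self):
        if self.variant not in ("generic", "riu2"):
            raise ValueError(f"unknown variant {self.variant!r}")
        codes = np.asarray(self.codes)
        hi = 2 ** self.config.p - 1 if self.variant == "generic" else self.config.p + 1
        if codes.size and (codes.min() < 0 or codes.max() > hi):
            raise ValueError("codes out of range for variant")
        object.__setattr__(self, "codes", codes)

    @property
    def n_bins(self) -> int:
        return 2 ** self.config.p if self.variant == "generic" else self.config.p + 2


@dataclass(frozen=True)
class TextureHistogram:
    """Fixed-bin descriptor histogram for one image."""

    bins: np.ndarray
    descriptor: str
    normalized: bool

    def __post_init__(self):
        object.__setattr__(self, "bins", np.asarray(self.bins, dtype=float))

    def __len__(self) -> int:
        return len(self.bins)


def _bilinear(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Sample ``image`` at fractional (rows, cols); exact grid hits bypass interpolation."""
    r0 = np.floor(rows)
    c0 = np.floor(cols)
    dr = rows - r0
    dc = cols - c0
    # snap near-integer coordinates to kill float drift from sin/cos
    snap_r = np.abs(dr) < _GRID_EPS
    snap_c = np.abs(dc) < _GRID_EPS
    dr = np.where(snap_r, 0.0, dr)
    dc = np.where(snap_c, 0.0, dc)
    snap_r_hi = np.abs(dr - 1.0) < _GRID_EPS
    snap_c_hi = np.abs(dc - 1.0) < _GRID_EPS
    r0 = np.where(snap_r_hi, r0 + 1, r0).astype(int)
    c0 = np.where(snap_c_hi, c0 + 1, c0).astype(int)
    dr = np.where(snap_r_hi, 0.0, dr)
    dc = np.where(snap_c_hi, 0.0, dc)
    r1 = np.minimum(r0 + 1, image.shape[0] - 1)
    c1 = np.minimum(c0 + 1, image.shape[1] - 1)
    top = image[r0, c0] * (1 - dc) + image[r0, c1] * dc
    bot = image[r1, c0] * (1 - dc) + image[r1, c1] * dc
    return top * (1 - dr) + bot * dr


def sample_neighbourhood(
    image: np.ndarray, centre: tuple[int, int], config: CircularNeighbourhoodConfig
) -> np.ndarray:
    """Grey values of the ``p`` circular neighbours of ``centre``."""
    image = np.asarray(image, dtype=float)
    row, col = centre
    m = config.margin
    if not (m <= row < image.shape[0] - m and m <= col < image.shape[1] - m):
        raise IndexError(f"centre {centre} closer than ceil(r)={m} to a border of {image.shape}")
    offs = config.offsets()
    return _bilinear(image, row + offs[:, 0], col + offs[:, 1])


def lbp_code(gc: float, neighbours: np.ndarray) -> int:
    """Generic LBP code: sum of ``2**n`` over neighbours with ``g_n >= g_c``."""
    bits = np.asarray(neighbours, dtype=float) - float(gc) >= 0
    return int(np.sum(bits * (1 << np.arange(len(bits), dtype=object))))


def ror_min(code: int, p: int) -> tuple[int, int]:
    """Minimum over all ``p`` circular right rotations of ``code`` and the
    smallest step count achieving it."""
    if not 0 <= code < 2 ** p:
        raise ValueError(f"code {code} out of range for p={p}")
    mask = 2 ** p - 1
    best, best_steps = code, 0
    c = code
    for n in range(1, p):
        c = ((c >> 1) | (c << (p - 1))) & mask
        if c < best:
            best, best_steps = c, n
    return best, best_steps


def uniformity(code: int, p: int) -> int:
    """Number of circular 0<->1 transitions in the ``p``-bit pattern."""
    if not 0 <= code < 2 ** p:
        raise ValueError(f"code {code} out of range for p={p}")
    bits = [(code >> n) & 1 for n in range(p)]
    u = abs(bits[p - 1] - bits[0])
    for n in range(1, p):
        u += abs(bits[n] - bits[n - 1])
    return u


def riu2_code(code: int, p: int) -> int:
    """Rotation-invariant-uniform label: bit count if uniformity <= 2, else ``p + 1``."""
    if uniformity(code, p) <= 2:
        return bin(code).count("1")
    return p + 1


def _riu2_lut(p: int) -> np.ndarray:
    lut = np.empty(2 ** p, dtype=np.int64)
    for c in range(2 ** p):
        lut[c] = riu2_code(c, p)
    return lut


_LUT_CACHE: dict[int, np.ndarray] = {}


def dense_code_map(image: np.ndarray, config: CircularNeighbourhoodConfig, variant: str = "riu2") -> LbpCodeImage:
    """Code every interior pixel of ``image`` (margin of ``ceil(r)`` excluded)."""
    image = np.asarray(image, dtype=float)
    m = config.margin
    h, w = image.shape
    if h <= 2 * m + 1 or w <= 2 * m + 1:
        raise ValueError(f"image {image.shape} too small for margin {m}")
    centre = image[m : h - m, m : w - m]
    rows, cols = np.meshgrid(
        np.arange(m, h - m, dtype=float), np.arange(m, w - m, dtype=float), indexing="ij"
    )
    codes = np.zeros(centre.shape, dtype=np.int64)
    for n, (dr, dc) in enumerate(config.offsets()):
        gn = _bilinear(image, rows + dr, cols + dc)
        codes |= (gn - centre >= 0).astype(np.int64) << n
    if variant == "riu2":
        lut = _LUT_CACHE.get(config.p)
        if lut is None:
            lut = _LUT_CACHE.setdefault(config.p, _riu2_lut(config.p))
        codes = lut[codes]
    elif variant != "generic":
        raise ValueError(f"unknown variant {variant!r}")
    return LbpCodeImage(codes=codes, variant=variant, config=config)


def histogram(code_image: LbpCodeImage, normalize: bool = True) -> TextureHistogram:
    """Per-image histogram over the variant's full code range."""
    n_bins = code_image.n_bins
    counts = np.bincount(code_image.codes.ravel(), minlength=n_bins).astype(float)
    if len(counts) > n_bins:
        raise RuntimeError("code out of range for variant")  # guarded by LbpCodeImage
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    tag = f"lbp_{code_image.variant}_p{code_image.config.p}_r{code_image.config.r:g}"
    return TextureHistogram(bins=counts, descriptor=tag, normalized=normalize)
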