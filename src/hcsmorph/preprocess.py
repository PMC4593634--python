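"""Micrograph preprocessing: grayscale conversion, intensity normalization,
2x down-sampling, Otsu binarization and small-object removal.

The output of :func:`preprocess` is a :class:`PreprocessedImage` -- a paired
16-bit-range grayscale image and binary foreground mask from which all
downstream features are computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi

__all__ = [
    "RawImage",
    "PreprocessedImage",
    "PreprocessConfig",
    "to_grayscale",
    "normalize_intensity",
    "downsample",
    "binarize_otsu",
    "remove_small_objects",
    "preprocess",
]

log = logging.getLogger(__name__)

INTENSITY_MAX = 65535
OTSU_BINS = 256

#: BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class RawImage:
    """An RGB micrograph (8 bits per channel) plus a provenance label."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 RGB array, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"image too small: {px.shape[0]}x{px.shape[1]}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PreprocessedImage:
    """Paired normalized grayscale image and binary foreground mask.

    ``gray`` holds integer-valued intensities in ``[0, 65535]`` with the
    background (mask == 0) zeroed; ``mask`` is boolean.
    """

    gray: np.ndarray
    mask: np.ndarray
    otsu_threshold: float
    removed_objects: int = 0
    source_id: str = ""
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.gray.shape != self.mask.shape:
            raise ValueError("gray and mask must share dimensions")

    @property
    def height(self) -> int:
        return self.gray.shape[0]

    @property
    def width(self) -> int:
        return self.gray.shape[1]

    @property
    def binary(self) -> np.ndarray:
        """Mask as a float {0,1} image (for moment computations)."""
        return self.mask.astype(np.float64)


@dataclass
class PreprocessConfig:
    gray_mode: str = "luminance"  # "luminance" | "green" | "red" | "blue"
    min_object_size: int = 50  # strict: components with area < 50 removed
    downsample: bool = True


def to_grayscale(raw: RawImage, mode: str = "luminance") -> np.ndarray:
    """Convert an RGB image to a single channel.

    ``luminance`` uses BT.601 weights; ``green``/``red``/``blue`` pick a
    single channel (green is appropriate for FITC-stained images).
    """
    px = raw.pixels.astype(np.float64)
    if mode == "luminance":
        w = LUMA_WEIGHTS
        return px[..., 0] * w[0] + px[..., 1] * w[1] + px[..., 2] * w[2]
    channels = {"red": 0, "green": 1, "blue": 2}
    if mode not in channels:
        raise ValueError(f"unknown gray mode {mode!r}")
    return px[..., channels[mode]]


def normalize_intensity(gray: np.ndarray) -> np.ndarray:
    """Linearly rescale intensities onto ``[0, 65535]`` (rounded to integers).

    A constant image maps to all zeros (documented convention).
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.size == 0:
        raise ValueError("empty image")
    lo, hi = gray.min(), gray.max()
    if hi == lo:
        log.warning("constant image: normalization maps to zeros")
        return np.zeros_like(gray)
    return np.rint((gray - lo) * (INTENSITY_MAX / (hi - lo)))


def downsample(gray: np.ndarray) -> np.ndarray:
    """Halve both dimensions by 2x2 block averaging (rounded).

    Odd dimensions are padded by edge replication first (logged).
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    if h % 2 or w % 2:
        log.warning("odd dimensions %dx%d padded by replication", h, w)
        gray = np.pad(gray, ((0, h % 2), (0, w % 2)), mode="edge")
        h, w = gray.shape
    blocks = gray.reshape(h // 2, 2, w // 2, 2)
    return np.rint(blocks.mean(axis=(1, 3)))


def _otsu_histogram(gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.linspace(0.0, float(INTENSITY_MAX), OTSU_BINS + 1)
    hist, _ = np.histogram(gray, bins=edges)
    return hist.astype(np.float64), edges


def binarize_otsu(gray: np.ndarray) -> tuple[np.ndarray, float]:
    """Otsu threshold over a fixed 256-bin histogram of ``[0, 65535]``.

    Returns ``(mask, threshold)`` where ``mask = gray > threshold``.  The
    threshold is the upper edge of the selected bin, so it maximizes the
    between-class variance over the 256 candidate splits.  A constant image
    yields an all-background mask and a NaN threshold.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if np.ptp(gray) == 0:
        log.warning("constant image: empty Otsu mask")
        return np.zeros(gray.shape, dtype=bool), math.nan
    hist, edges = _otsu_histogram(gray)
    n = hist.sum()
    p = hist / n
    omega = np.cumsum(p)
    mu = np.cumsum(p * np.arange(OTSU_BINS))
    mu_t = mu[-1]
    # between-class variance for split after bin t (t = 0..254)
    w0 = omega[:-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu[:-1]) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    t_idx = int(np.argmax(sigma_b))
    threshold = float(edges[t_idx + 1])
    # bin membership, not float comparison, decides foreground
    idx = np.minimum((gray * (OTSU_BINS / (INTENSITY_MAX + 1e-9))).astype(int), OTSU_BINS - 1)
    mask = idx > t_idx
    return mask, threshold


def remove_small_objects(mask: np.ndarray, min_size: int = 50) -> np.ndarray:
    """Drop 8-connected components with area strictly below ``min_size``."""
    mask = np.asarray(mask, dtype=bool)
    if min_size <= 1:
        return mask.copy()
    labels, num = _ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    if num == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    keep = areas >= min_size
    return keep[labels]


def _count_components(mask: np.ndarray) -> int:
    _, num = _ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    return int(num)


def preprocess(raw: RawImage, config: PreprocessConfig | None = None) -> PreprocessedImage:
    """Run the full preprocessing chain on one raw micrograph.

    Order: grayscale -> normalize -> 2x down-sample -> renormalize ->
    Otsu binarization -> small-object removal -> background suppression.
    The renormalization restores the exact ``[0, 65535]`` range after block
    averaging.  Object removal operates on the down-sampled (800x600 scale)
    mask; the same Otsu threshold serves both the binary conversion and the
    background suppression of the gray image.
    """
    config = config or PreprocessConfig()
    flags: list[str] = []
    gray = to_grayscale(raw, config.gray_mode)
    gray = normalize_intensity(gray)
    if config.downsample:
        gray = downsample(gray)
        gray = normalize_intensity(gray)
    mask, threshold = binarize_otsu(gray)
    if math.isnan(threshold):
        flags.append("constant_image")
    n_before = _count_components(mask)
    mask = remove_small_objects(mask, config.min_object_size)
    removed = n_before - _count_components(mask)
    gray = np.where(mask, gray, 0.0)
    return PreprocessedImage(
        gray=gray,
        mask=mask,
        otsu_threshold=threshold,
        removed_objects=removed,
        source_id=raw.source_id,
        flags=flags,
    )
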