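"""Named whole-image features: the five neuronal measurements and the
human-interpretable descriptor families (Pixel Area, Pixel Area Ring,
Texture Area / Texture Area Variation, Texture Information, Different Pixel
Area, Cell Distribution X/Y).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as _ndi
from skimage import measure

from .moments import geometric_moment
from .texture import DEFAULT_ANGLES, glcm, quantize

__all__ = ["neuronal_features", "interpretable_features", "NEURONAL_NAMES",
           "CELL_DISTRIBUTION_ORDERS"]

_STRUCT8 = np.ones((3, 3), dtype=int)

NEURONAL_NAMES = (
    "Mean Cell Intensity",
    "Cell Number",
    "Total Cell Area",
    "Largest Cell Area",
    "Largest Cell Diameter",
)

#: Cell Distribution X/Y exposes normalized geometric moments at these orders.
CELL_DISTRIBUTION_ORDERS = ((0, 2), (2, 0), (1, 1), (0, 3), (3, 0), (1, 2), (2, 1), (2, 2))


def neuronal_features(gray: np.ndarray, mask: np.ndarray,
                      diameter: str = "feret") -> dict[str, float]:
    """The five neuronal measurements of one preprocessed pair.

    ``diameter`` selects the Largest Cell Diameter convention: maximum Feret
    diameter (default) or ``"equivalent"`` circle diameter.
    """
    g = np.asarray(gray, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return {name: 0.0 for name in NEURONAL_NAMES}
    labels, num = _ndi.label(m, structure=_STRUCT8)
    props = measure.regionprops(labels)
    areas = [p.area for p in props]
    largest = props[int(np.argmax(areas))]
    if diameter == "feret":
        diam = float(largest.feret_diameter_max)
    elif diameter == "equivalent":
        diam = float(largest.equivalent_diameter_area)
    else:
        raise ValueError(f"unknown diameter convention {diameter!r}")
    return {
        "Mean Cell Intensity": float(g[m].mean()),
        "Cell Number": float(num),
        "Total Cell Area": float(m.sum()),
        "Largest Cell Area": float(max(areas)),
        "Largest Cell Diameter": diam,
    }


def _pixel_area(gray: np.ndarray, mask: np.ndarray, bins: int) -> dict[str, float]:
    vals = np.asarray(gray, dtype=np.float64)[np.asarray(mask, dtype=bool)]
    counts, _ = np.histogram(vals, bins=bins, range=(0.0, 65536.0))
    return {f"Pixel Area ({k})": float(counts[k]) for k in range(bins)}


def _pixel_area_ring(mask: np.ndarray, n_rings: int) -> dict[str, float]:
    m = np.asarray(mask, dtype=bool)
    out = {f"Pixel Area Ring ({r})": 0.0 for r in range(n_rings)}
    if not m.any():
        return out
    ys, xs = np.nonzero(m)
    yc, xc = ys.mean(), xs.mean()
    rr = np.hypot(xs - xc, ys - yc)
    rmax = math.hypot(*m.shape) / 2.0
    rbin = np.minimum((rr / rmax * n_rings).astype(int), n_rings - 1)
    counts = np.bincount(rbin, minlength=n_rings)
    for r in range(n_rings):
        out[f"Pixel Area Ring ({r})"] = float(counts[r])
    return out


def _texture_area(gray: np.ndarray, distances, diff_bins: int,
                  levels: int) -> dict[str, float]:
    """Counts of pixel pairs whose quantized-intensity difference falls in a
    given bin, per (distance, direction), plus the variance of each count
    across the four directions (Texture Area Variation)."""
    g = np.asarray(gray, dtype=np.float64)
    out: dict[str, float] = {}
    q = quantize(g, levels).astype(np.int64)
    h, w = q.shape
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0, 45, 90, 135 degrees
    edges = np.linspace(0, levels, diff_bins + 1)
    for d in distances:
        counts = np.zeros((len(offsets), diff_bins))
        for a, (dy, dx) in enumerate(offsets):
            sy, sx = dy * d, dx * d
            y0, y1 = max(0, -sy), min(h, h - sy)
            x0, x1 = max(0, -sx), min(w, w - sx)
            if y0 >= y1 or x0 >= x1:
                continue
            diff = np.abs(q[y0:y1, x0:x1] - q[y0 + sy:y1 + sy, x0 + sx:x1 + sx])
            hist, _ = np.histogram(diff, bins=edges)
            counts[a] = hist
        for a in range(len(offsets)):
            for t in range(diff_bins):
                out[f"Texture Area ({d}, {a}, {t})"] = float(counts[a, t])
        for t in range(diff_bins):
            out[f"Texture Area Variation ({d}, {t})"] = float(counts[:, t].var())
    return out


def _texture_information(gray: np.ndarray, distances, levels: int) -> dict[str, float]:
    """Entropy of the GLCM at each (distance, angle) configuration ``k``."""
    g = np.asarray(gray, dtype=np.float64)
    n_cfg = len(distances) * len(DEFAULT_ANGLES)
    if not g.any():  # empty image
        return {f"Texture Information ({k})": 0.0 for k in range(n_cfg)}
    q = quantize(g, levels)
    P = glcm(q, distances, DEFAULT_ANGLES, levels)
    out = {}
    k = 0
    for di in range(len(distances)):
        for ai in range(len(DEFAULT_ANGLES)):
            p = P[:, :, di, ai]
            out[f"Texture Information ({k})"] = float(-(p * np.log2(p + 1e-12)).sum())
            k += 1
    return out


def _different_pixel_area(gray: np.ndarray, bins: int, window: int) -> dict[str, float]:
    """Counts of pixels by (gray - local mean background) difference bin."""
    g = np.asarray(gray, dtype=np.float64)
    local = _ndi.uniform_filter(g, size=window, mode="reflect")
    diff = g - local
    counts, _ = np.histogram(diff, bins=bins, range=(-65535.0, 65535.0))
    return {f"Different Pixel Area ({k})": float(counts[k]) for k in range(bins)}


def _cell_distribution(image: np.ndarray, prefix: str) -> dict[str, float]:
    out = {}
    for (i, j) in CELL_DISTRIBUTION_ORDERS:
        out[f"{prefix} ({i}, {j})"] = geometric_moment(image, i, j, normalized=True)
    return out


def interpretable_features(gray: np.ndarray, mask: np.ndarray,
                           pixel_area_bins: int = 128,
                           n_rings: int = 64,
                           texture_distances=(1, 3, 5),
                           texture_diff_bins: int = 8,
                           texture_levels: int = 16,
                           dpa_bins: int = 32,
                           dpa_window: int = 15) -> dict[str, float]:
    """All interpretable descriptors of one preprocessed gray/mask pair."""
    out: dict[str, float] = {}
    out.update(_pixel_area(gray, mask, pixel_area_bins))
    out.update(_pixel_area_ring(mask, n_rings))
    out.update(_texture_area(gray, texture_distances, texture_diff_bins, texture_levels))
    out.update(_texture_information(gray, texture_distances, texture_levels))
    out.update(_different_pixel_area(gray, dpa_bins, dpa_window))
    out.update(_cell_distribution(np.asarray(mask, dtype=np.float64), "Cell Distribution X/Y"))
    out.update(_cell_distribution(np.asarray(gray, dtype=np.float64), "Cell Distribution Gray X/Y"))
    return out
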