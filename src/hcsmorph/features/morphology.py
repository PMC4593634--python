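"""Morphology features: square/polar shape matrices and region properties."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as _ndi
from skimage import measure

__all__ = ["square_shape_matrix", "polar_shape_matrix", "region_property_features",
           "morphology_features"]

_STRUCT8 = np.ones((3, 3), dtype=int)


def square_shape_matrix(mask: np.ndarray, size: int = 8) -> np.ndarray:
    """Binary silhouette resampled onto a ``size x size`` square grid.

    The mask bounding box is split into a ``size x size`` grid of blocks;
    each cell is 1 when at least half of its block is foreground.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros((size, size), dtype=np.uint8)
    ys, xs = np.nonzero(mask)
    sub = mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1].astype(np.float64)
    h, w = sub.shape
    out = np.zeros((size, size), dtype=np.uint8)
    ye = np.linspace(0, h, size + 1)
    xe = np.linspace(0, w, size + 1)
    for a in range(size):
        for b in range(size):
            block = sub[int(ye[a]):max(int(ye[a + 1]), int(ye[a]) + 1),
                        int(xe[b]):max(int(xe[b + 1]), int(xe[b]) + 1)]
            out[a, b] = 1 if block.mean() >= 0.5 else 0
    return out


def polar_shape_matrix(mask: np.ndarray, n_r: int = 8, n_theta: int = 8) -> np.ndarray:
    """Binary occupancy of the silhouette on a polar grid about its centroid."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros((n_r, n_theta), dtype=np.uint8)
    if not mask.any():
        return out
    ys, xs = np.nonzero(mask)
    yc, xc = ys.mean(), xs.mean()
    r = np.hypot(xs - xc, ys - yc)
    rmax = r.max()
    if rmax == 0:
        out[0, :] = 1
        return out
    rbin = np.minimum((r / rmax * n_r).astype(int), n_r - 1)
    theta = np.arctan2(ys - yc, xs - xc)  # [-pi, pi)
    tbin = np.minimum(((theta + np.pi) / (2 * np.pi) * n_theta).astype(int), n_theta - 1)
    out[rbin, tbin] = 1
    return out


def region_property_features(mask: np.ndarray) -> dict[str, float]:
    """Per-component area/eccentricity/solidity/perimeter aggregated over components."""
    mask = np.asarray(mask, dtype=bool)
    labels, num = _ndi.label(mask, structure=_STRUCT8)
    out: dict[str, float] = {"Region count": float(num)}
    props = measure.regionprops(labels) if num else []
    quantities = {
        "area": [p.area for p in props],
        "eccentricity": [p.eccentricity for p in props],
        "solidity": [p.solidity for p in props],
        "perimeter": [p.perimeter for p in props],
    }
    for name, vals in quantities.items():
        arr = np.asarray(vals, dtype=np.float64)
        out[f"Region {name} mean"] = float(arr.mean()) if num else 0.0
        out[f"Region {name} max"] = float(arr.max()) if num else 0.0
        if name in ("area", "perimeter"):
            out[f"Region {name} total"] = float(arr.sum()) if num else 0.0
    return out


def morphology_features(mask: np.ndarray, shape_size: int = 8, n_r: int = 8,
                        n_theta: int = 8) -> dict[str, float]:
    """All morphology descriptors of one binary mask."""
    out: dict[str, float] = {}
    sq = square_shape_matrix(mask, shape_size)
    for a in range(shape_size):
        for b in range(shape_size):
            out[f"Square Shape ({a}, {b})"] = float(sq[a, b])
    pol = polar_shape_matrix(mask, n_r, n_theta)
    for a in range(n_r):
        for b in range(n_theta):
            out[f"Polar Shape ({a}, {b})"] = float(pol[a, b])
    out.update(region_property_features(mask))
    return out
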