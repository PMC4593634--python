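"""Gray-level co-occurrence texture features (GLCM entries + Haralick statistics)."""

from __future__ import annotations

import numpy as np
from skimage.feature import graycomatrix

__all__ = ["quantize", "glcm", "haralick_from_glcm", "texture_features",
           "HARALICK_NAMES", "DEFAULT_DISTANCES", "DEFAULT_ANGLES"]

DEFAULT_LEVELS = 16
DEFAULT_DISTANCES = (1, 3, 5)
DEFAULT_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)

HARALICK_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_correlation_1",
    "info_correlation_2",
)

_EPS = 1e-12


def quantize(gray: np.ndarray, levels: int = DEFAULT_LEVELS,
             max_intensity: float = 65535.0) -> np.ndarray:
    """Quantize intensities in [0, max_intensity] to ``levels`` integer levels."""
    g = np.asarray(gray, dtype=np.float64)
    q = np.floor(g * (levels / (max_intensity + 1e-9))).astype(np.uint8)
    return np.minimum(q, levels - 1)


def glcm(quantized: np.ndarray, distances=DEFAULT_DISTANCES, angles=DEFAULT_ANGLES,
         levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix, shape (levels, levels, D, A)."""
    return graycomatrix(quantized, distances=list(distances), angles=list(angles),
                        levels=levels, symmetric=True, normed=True)


def haralick_from_glcm(P: np.ndarray) -> dict[str, float]:
    """The 13 Haralick statistics of one normalized, symmetric GLCM."""
    P = np.asarray(P, dtype=np.float64)
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = (i * px).sum()
    var = ((i - mu) ** 2 * px).sum()

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), P.ravel())
    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(ii - jj).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_diff = np.arange(L, dtype=np.float64)

    energy = float((P**2).sum())
    contrast = float((pdiff * k_diff**2).sum())
    correlation = float(((ii - mu) * (jj - mu) * P).sum() / var) if var > _EPS else 0.0
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    entropy = float(-(P * np.log2(P + _EPS)).sum())
    sum_average = float((k_sum * psum).sum())
    sum_entropy = float(-(psum * np.log2(psum + _EPS)).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * psum).sum())
    diff_entropy = float(-(pdiff * np.log2(pdiff + _EPS)).sum())
    diff_mean = float((k_diff * pdiff).sum())
    diff_variance = float(((k_diff - diff_mean) ** 2 * pdiff).sum())

    hx = float(-(px * np.log2(px + _EPS)).sum())
    pxy = np.outer(px, px)
    hxy1 = float(-(P * np.log2(pxy + _EPS)).sum())
    hxy2 = float(-(pxy * np.log2(pxy + _EPS)).sum())
    denom = max(hx, _EPS)
    info_corr_1 = (entropy - hxy1) / denom
    info_corr_2 = math_sqrt_clipped(1.0 - np.exp(-2.0 * (hxy2 - entropy)))

    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "variance": float(var),
        "homogeneity": homogeneity,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": diff_variance,
        "difference_entropy": diff_entropy,
        "info_correlation_1": float(info_corr_1),
        "info_correlation_2": float(info_corr_2),
    }


def math_sqrt_clipped(v: float) -> float:
    return float(np.sqrt(max(v, 0.0)))


def texture_features(gray: np.ndarray, distances=DEFAULT_DISTANCES,
                     angles=DEFAULT_ANGLES, levels: int = DEFAULT_LEVELS,
                     include_glcm_entries: bool = True,
                     glcm_entry_distances=(1,)) -> dict[str, float]:
    """Haralick statistics per distance (averaged over angles) plus, optionally,
    the angle-averaged GLCM entries themselves at selected distances.

    An empty (constant-zero) image yields all-zero values.
    """
    g = np.asarray(gray, dtype=np.float64)
    out: dict[str, float] = {}
    degenerate = not g.any()  # empty image -> all zeros (flagged upstream)
    q = quantize(g, levels)
    P = None if degenerate else glcm(q, distances, angles, levels)
    for d_idx, d in enumerate(distances):
        if degenerate:
            stats = {k: 0.0 for k in HARALICK_NAMES}
        else:
            per_angle = [haralick_from_glcm(P[:, :, d_idx, a]) for a in range(len(angles))]
            stats = {k: float(np.mean([s[k] for s in per_angle])) for k in HARALICK_NAMES}
        for k in HARALICK_NAMES:
            out[f"Haralick {k} (d={d})"] = stats[k]
    if include_glcm_entries:
        for d in glcm_entry_distances:
            d_idx = list(distances).index(d)
            if degenerate:
                mean_P = np.zeros((levels, levels))
            else:
                mean_P = P[:, :, d_idx, :].mean(axis=2)
            for a in range(levels):
                for b in range(a, levels):
                    out[f"GLCM ({d}, {a}, {b})"] = float(mean_P[a, b])
    return out
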