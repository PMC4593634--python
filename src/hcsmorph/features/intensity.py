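"""Intensity histogram features."""

from __future__ import annotations

import numpy as np

__all__ = ["intensity_features"]


def intensity_features(gray: np.ndarray, bins: int = 32,
                       max_intensity: float = 65535.0) -> dict[str, float]:
    """Absolute and relative (sum-to-1) histograms over ``[0, max_intensity]``."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    g = np.asarray(gray, dtype=np.float64)
    counts, _ = np.histogram(g, bins=bins, range=(0.0, max_intensity + 1.0))
    total = counts.sum()
    rel = counts / total if total else np.zeros_like(counts, dtype=float)
    out: dict[str, float] = {}
    for k in range(bins):
        out[f"Histogram ({k})"] = float(counts[k])
    for k in range(bins):
        out[f"Relative Histogram ({k})"] = float(rel[k])
    return out
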