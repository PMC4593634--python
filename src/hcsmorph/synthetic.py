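"""Synthetic two-class immunostaining-like image and feature-table generators.

Images are rendered as Gaussian-smoothed ellipses ("cells") on a noisy
background with optional sub-threshold speckles; three phenotype knobs map
onto the contrasts the pipeline is designed to detect: ``intensity_mean``
(mean cell intensity), ``cell_radius_mean`` (total foreground area) and
``aggregation`` (spatial clustering, lowering the normalized second-order
geometric moment).  All randomness flows from explicit seeds through
``numpy.random.default_rng`` (PCG64), so datasets are reproducible across
platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as _ndi

from .features.extract import LABEL_NEURO, LABEL_NON
from .preprocess import RawImage

__all__ = ["PhenotypeParams", "SyntheticDataset", "render_image",
           "make_two_class_study", "make_feature_table", "preset_params"]


@dataclass
class PhenotypeParams:
    n_cells: int = 20
    cell_radius_mean: float = 6.0
    cell_radius_sd: float = 1.5
    intensity_mean: float = 150.0  # 8-bit canvas units
    intensity_sd: float = 25.0
    aggregation: float = 0.0  # 0 = uniform placement, 1 = tight clusters
    n_clusters: int = 3
    background_noise_sd: float = 8.0
    speckle_rate: float = 10.0  # expected sub-threshold speckles per image
    width: int = 320
    height: int = 240
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.aggregation <= 1.0:
            raise ValueError("aggregation must lie in [0, 1]")
        for attr in ("n_cells", "cell_radius_mean", "intensity_mean", "width", "height"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")


@dataclass
class SyntheticDataset:
    images: list  # list[RawImage]
    labels: list  # class label per image
    ground_truth: list  # dict per image
    params_per_class: dict = field(default_factory=dict)


def _place_cells(params: PhenotypeParams, rng: np.random.Generator) -> np.ndarray:
    """Cell centres: uniform at aggregation 0, tight clusters at 1."""
    w, h = params.width, params.height
    margin = params.cell_radius_mean + 3 * params.cell_radius_sd
    lo = np.array([margin, margin])
    hi = np.array([w - margin, h - margin])
    centers = rng.uniform(lo, hi, size=(params.n_clusters, 2))
    # aggregation both tightens cells around their cluster centre and pulls
    # the cluster centres together, so overall spatial variance shrinks
    mid = np.array([w / 2.0, h / 2.0])
    centers = mid + (centers - mid) * (1.0 - 0.8 * params.aggregation)
    sigma_max = 0.5 * min(w, h)
    sigma_min = 1.5 * params.cell_radius_mean
    sigma = sigma_max * (1 - params.aggregation) + sigma_min * params.aggregation
    out = np.empty((params.n_cells, 2))
    for i in range(params.n_cells):
        c = centers[rng.integers(params.n_clusters)]
        for _ in range(50):  # rejection sampling against the canvas
            pos = c + rng.normal(0.0, sigma, size=2)
            if (pos >= lo).all() and (pos <= hi).all():
                break
        else:
            pos = np.clip(pos, lo, hi)
        out[i] = pos
    return out


def render_image(params: PhenotypeParams,
                 rng: np.random.Generator | None = None) -> tuple[RawImage, dict]:
    """Render one image plus its ground truth (count, area, centroids)."""
    rng = rng or np.random.default_rng(params.rng_seed)
    w, h = params.width, params.height
    canvas = np.zeros((h, w), dtype=np.float64)
    yy, xx = np.indices((h, w))
    centers = _place_cells(params, rng) if params.n_cells else np.empty((0, 2))
    areas = []
    for cx, cy in centers:
        a = max(2.0, rng.normal(params.cell_radius_mean, params.cell_radius_sd))
        b = a * rng.uniform(0.7, 1.0)
        phi = rng.uniform(0, math.pi)
        inten = max(20.0, rng.normal(params.intensity_mean, params.intensity_sd))
        dx, dy = xx - cx, yy - cy
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        cell = ((u / a) ** 2 + (v / b) ** 2) <= 1.0
        canvas = np.maximum(canvas, cell * inten)
        areas.append(math.pi * a * b)
    canvas = _ndi.gaussian_filter(canvas, sigma=1.2)
    # sub-threshold speckles (small objects the preprocessing should remove)
    n_speckles = int(rng.poisson(params.speckle_rate))
    for _ in range(n_speckles):
        sy = rng.integers(1, h - 1)
        sx = rng.integers(1, w - 1)
        size = int(rng.integers(1, 4))
        canvas[sy:sy + size, sx:sx + size] = np.maximum(
            canvas[sy:sy + size, sx:sx + size], params.intensity_mean)
    if params.background_noise_sd > 0:
        canvas += np.abs(rng.normal(0.0, params.background_noise_sd, size=(h, w)))
    canvas = np.clip(canvas, 0, 255)
    # FITC-like: signal mostly in the green channel
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[..., 1] = np.round(canvas).astype(np.uint8)
    rgb[..., 0] = np.round(0.15 * canvas).astype(np.uint8)
    rgb[..., 2] = np.round(0.10 * canvas).astype(np.uint8)
    truth = {
        "n_cells": int(params.n_cells),
        "total_area": float(sum(areas)),
        "centroids": centers.tolist(),
        "centroid_scatter": float(np.var(centers, axis=0).sum()) if len(centers) else 0.0,
        "n_speckles": n_speckles,
    }
    return RawImage(pixels=rgb), truth


def make_two_class_study(control: PhenotypeParams, case: PhenotypeParams,
                         n_per_class: int = 15,
                         seed: int | None = None) -> SyntheticDataset:
    """Balanced labeled image set: control -> non-neuroinflammation,
    case -> neuroinflammation."""
    seed = control.rng_seed if seed is None else seed
    seeds = np.random.SeedSequence(seed).spawn(2 * n_per_class)
    images, labels, truths = [], [], []
    for i in range(n_per_class):
        for params, label, tag in ((control, LABEL_NON, "ctrl"),
                                   (case, LABEL_NEURO, "case")):
            k = 2 * i + (0 if tag == "ctrl" else 1)
            rng = np.random.default_rng(seeds[k])
            img, truth = render_image(params, rng)
            img.source_id = f"{tag}_{i:03d}"
            images.append(img)
            labels.append(label)
            truths.append(truth)
    return SyntheticDataset(images=images, labels=labels, ground_truth=truths,
                            params_per_class={LABEL_NON: control, LABEL_NEURO: case})


def preset_params(preset: str, seed: int = 0, **overrides) -> tuple[PhenotypeParams, PhenotypeParams]:
    """(control, case) parameter pairs for the named study preset.

    ``astrocyte``: case has brighter, larger, more aggregated cells;
    ``microglia``: intensity shift only; ``null``: identical classes.
    """
    base = PhenotypeParams(rng_seed=seed, **overrides)
    if preset == "astrocyte":
        case = replace(base, intensity_mean=base.intensity_mean * 1.45,
                       cell_radius_mean=base.cell_radius_mean * 1.4,
                       aggregation=0.8)
    elif preset == "microglia":
        case = replace(base, intensity_mean=base.intensity_mean * 1.3)
    elif preset == "null":
        case = replace(base)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return base, case


def make_feature_table(n_samples: int, n_features: int = 40, planted=(),
                       effect_size: float = 0.0, seed: int = 0,
                       n_neuronal: int = 0):
    """Gaussian feature table with ``planted`` features shifted by
    ``effect_size`` (in SD units) in the case class.  Optionally tags the
    last ``n_neuronal`` features as neuronal and a third of the rest as
    interpretable, so selection quotas can be exercised.
    """
    from .features.extract import FeatureDescriptor, FeatureTable
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_case = n_samples // 2
    labels = np.array([LABEL_NON] * (n_samples - n_case) + [LABEL_NEURO] * n_case)
    X = rng.standard_normal((n_samples, n_features))
    for f in planted:
        X[labels == LABEL_NEURO, f] += effect_size
    names = [f"F{k:04d}" for k in range(n_features)]
    descs = []
    for k, name in enumerate(names):
        if k >= n_features - n_neuronal:
            cat = "neuronal"
        elif k % 3 == 0:
            cat = "interpretable"
        else:
            cat = "computational"
        descs.append(FeatureDescriptor(name=name, family="synthetic",
                                       category=cat, source="gray"))
    df = pd.DataFrame(X, columns=names,
                      index=[f"s{k:03d}" for k in range(n_samples)])
    return FeatureTable(df, pd.Series(labels, index=df.index), descs)
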