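"""Feature-vector assembly: descriptor manifest, per-image extraction and the
samples x features table used by selection and modeling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ..preprocess import PreprocessedImage
from . import moments as _mom
from .frequency import frequency_features
from .intensity import intensity_features
from .morphology import morphology_features
from .named import interpretable_features, neuronal_features
from .texture import texture_features

__all__ = ["FeatureDescriptor", "FeatureVector", "FeatureTable",
           "ExtractionConfig", "build_manifest", "extract_all", "extract_table"]

LABEL_NEURO = "neuroinflammation"
LABEL_NON = "non_neuroinflammation"
LABEL_UNKNOWN = "unknown"

_FAMILY_TITLES = {
    "geometric": "Geometric",
    "legendre": "Legendre",
    "tchebichef": "Tchebichef",
    "krawtchouk": "Krawtchouk",
    "zernike": "Zernike",
    "pseudo_zernike": "Pseudo Zernike",
    "radial_tchebichef_fourier": "Radial Tchebichef Fourier",
    "fourier_mellin": "Fourier Mellin",
}


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str  # moment | texture | intensity | morphology | frequency | neuronal | interpretable
    category: str  # neuronal | interpretable | computational
    source: str  # gray | binary | pair
    params: tuple = ()


@dataclass
class FeatureVector:
    sample_id: str
    values: "pd.Series"
    label: str = LABEL_UNKNOWN
    flags: list = field(default_factory=list)


@dataclass
class ExtractionConfig:
    """Orders, bin counts and toggles for every feature family.

    The descriptor manifest, and hence the total feature count, is a pure
    function of this config.
    """

    moment_families: tuple = ("geometric", "legendre", "tchebichef", "krawtchouk",
                              "zernike", "pseudo_zernike",
                              "radial_tchebichef_fourier", "fourier_mellin")
    moment_orders: dict = field(default_factory=lambda: {
        "geometric": 3, "legendre": 8, "tchebichef": 8, "krawtchouk": 8,
        "zernike": 8, "pseudo_zernike": 6,
        "radial_tchebichef_fourier": 5, "fourier_mellin": 4,
    })
    texture: bool = True
    intensity: bool = True
    morphology: bool = True
    frequency: bool = True
    neuronal: bool = True
    interpretable: bool = True
    intensity_bins: int = 32
    pixel_area_bins: int = 128
    n_rings: int = 64
    gabor_frequencies: tuple = (0.1, 0.2, 0.3)
    wavelet_levels: int = 3

    def to_dict(self) -> dict:
        return asdict(self)


def _moment_block(image: np.ndarray, source_title: str,
                  config: ExtractionConfig) -> dict[str, float]:
    out: dict[str, float] = {}
    for family in config.moment_families:
        vals = _mom.moment_family(image, family, config.moment_orders[family])
        title = _FAMILY_TITLES[family]
        for (a, b), v in vals.items():
            out[f"{title} ({source_title}, {a}, {b})"] = v
    return out


def _compute_all(pre: PreprocessedImage, config: ExtractionConfig) -> dict[str, dict[str, float]]:
    """Per-block name -> value maps, keyed by block id (block order is fixed)."""
    gray = pre.gray
    binary = pre.binary
    blocks: dict[str, dict[str, float]] = {}
    if config.moment_families:
        blocks["moment_gray"] = _moment_block(gray, "Gray", config)
        blocks["moment_binary"] = _moment_block(binary, "Binary", config)
    if config.texture:
        blocks["texture"] = texture_features(gray)
    if config.intensity:
        blocks["intensity"] = intensity_features(gray, config.intensity_bins)
    if config.morphology:
        blocks["morphology"] = morphology_features(pre.mask)
    if config.frequency:
        blocks["frequency"] = frequency_features(
            gray, pre.mask, wavelet_levels=config.wavelet_levels,
            gabor_frequencies=config.gabor_frequencies)
    if config.neuronal:
        blocks["neuronal"] = neuronal_features(gray, pre.mask)
    if config.interpretable:
        blocks["interpretable"] = interpretable_features(
            gray, pre.mask, pixel_area_bins=config.pixel_area_bins,
            n_rings=config.n_rings)
    return blocks

_BLOCK_META = {
    # block id -> (family, category, source)
    "moment_gray": ("moment", "computational", "gray"),
    "moment_binary": ("moment", "computational", "binary"),
    "texture": ("texture", "computational", "gray"),
    "intensity": ("intensity", "interpretable", "gray"),
    "morphology": ("morphology", "computational", "binary"),
    "frequency": ("frequency", "computational", "pair"),
    "neuronal": ("neuronal", "neuronal", "pair"),
    "interpretable": ("interpretable", "interpretable", "pair"),
}

# interpretable exceptions inside otherwise-computational blocks
_INTERPRETABLE_PREFIXES = ("Region ",)


def _category_for(block: str, name: str) -> str:
    family, category, _ = _BLOCK_META[block]
    if block == "morphology" and name.startswith(_INTERPRETABLE_PREFIXES):
        return "interpretable"
    return category


def build_manifest(config: ExtractionConfig | None = None) -> list[FeatureDescriptor]:
    """Descriptor list for a config -- derived from a probe extraction on a
    tiny constant image, so names always match :func:`extract_all` output."""
    config = config or ExtractionConfig()
    probe = PreprocessedImage(
        gray=np.full((16, 16), 30000.0), mask=np.ones((16, 16), dtype=bool),
        otsu_threshold=0.0, source_id="__probe__")
    probe.gray[0, 0] = 65535.0  # avoid constant-image degeneracies
    blocks = _compute_all(probe, config)
    manifest: list[FeatureDescriptor] = []
    seen = set()
    for block, values in blocks.items():
        family, _, source = _BLOCK_META[block]
        for name in values:
            if name in seen:
                raise ValueError(f"duplicate feature name {name!r}")
            seen.add(name)
            manifest.append(FeatureDescriptor(
                name=name, family=family, category=_category_for(block, name),
                source=source))
    return manifest


def extract_all(pre: PreprocessedImage, config: ExtractionConfig | None = None,
                manifest: list[FeatureDescriptor] | None = None) -> FeatureVector:
    """Full feature vector of one preprocessed image, ordered by the manifest.

    Non-finite values are zeroed and flagged, so downstream selection never
    sees missing data.
    """
    config = config or ExtractionConfig()
    if manifest is None:
        manifest = build_manifest(config)
    blocks = _compute_all(pre, config)
    merged: dict[str, float] = {}
    for values in blocks.values():
        merged.update(values)
    names = [d.name for d in manifest]
    missing = [n for n in names if n not in merged]
    if missing:
        raise ValueError(f"extraction produced no value for: {missing[:5]} ...")
    vec = pd.Series([merged[n] for n in names], index=names, dtype=np.float64)
    flags = list(pre.flags)
    bad = ~np.isfinite(vec.to_numpy())
    if bad.any():
        flags.append(f"nonfinite:{int(bad.sum())}")
        vec[bad] = 0.0
    if not pre.mask.any():
        flags.append("empty_mask")
    return FeatureVector(sample_id=pre.source_id, values=vec, flags=flags)


class FeatureTable:
    """Samples x named features with class labels and descriptor metadata."""

    def __init__(self, X: pd.DataFrame, labels: pd.Series,
                 descriptors: list[FeatureDescriptor]):
        if not X.index.equals(labels.index):
            labels = labels.reindex(X.index)
        desc_names = [d.name for d in descriptors]
        if list(X.columns) != desc_names:
            raise ValueError("descriptor order must match table columns")
        if not np.isfinite(X.to_numpy()).all():
            raise ValueError("feature table contains non-finite values")
        self.X = X
        self.labels = labels.astype(str)
        self.descriptors = descriptors
        self._by_name = {d.name: d for d in descriptors}

    @classmethod
    def from_vectors(cls, vectors: list[FeatureVector],
                     descriptors: list[FeatureDescriptor]) -> "FeatureTable":
        X = pd.DataFrame([v.values for v in vectors],
                         index=[v.sample_id for v in vectors])
        labels = pd.Series([v.label for v in vectors], index=X.index)
        return cls(X, labels, descriptors)

    def __len__(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def class_counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def descriptor(self, name: str) -> FeatureDescriptor:
        return self._by_name[name]

    def subset(self, names: list[str]) -> "FeatureTable":
        descs = [self._by_name[n] for n in names]
        return FeatureTable(self.X[names].copy(), self.labels.copy(), descs)

    def to_csv(self, features_path, manifest_path=None) -> None:
        df = self.X.copy()
        df.insert(0, "label", self.labels)
        df.to_csv(features_path, index_label="sample_id")
        if manifest_path is not None:
            payload = [asdict(d) for d in self.descriptors]
            Path(manifest_path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def read_csv(cls, features_path, manifest_path=None) -> "FeatureTable":
        df = pd.read_csv(features_path, index_col="sample_id")
        labels = df.pop("label").astype(str)
        if manifest_path is not None:
            raw = json.loads(Path(manifest_path).read_text())
            descs = [FeatureDescriptor(name=d["name"], family=d["family"],
                                       category=d["category"], source=d["source"],
                                       params=tuple(d.get("params", ())))
                     for d in raw]
        else:
            descs = [FeatureDescriptor(name=c, family="unknown",
                                       category="computational", source="gray")
                     for c in df.columns]
        return cls(df, labels, descs)


def extract_table(pres: list[PreprocessedImage], labels: list[str],
                  config: ExtractionConfig | None = None) -> FeatureTable:
    """Extract every image and assemble the labeled feature table."""
    config = config or ExtractionConfig()
    manifest = build_manifest(config)
    vectors = []
    for pre, label in zip(pres, labels):
        v = extract_all(pre, config, manifest)
        v.label = label
        vectors.append(v)
    return FeatureTable.from_vectors(vectors, manifest)
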