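"""Readers and writers for raw micrographs and preprocessed image pairs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .preprocess import PreprocessedImage, RawImage

__all__ = ["read_raw", "write_raw", "write_preprocessed", "read_preprocessed",
           "iter_raw_dir"]

_RAW_EXTS = (".tif", ".tiff", ".png")


def read_raw(path) -> RawImage:
    """Load a TIFF/PNG image as RGB; grayscale inputs are replicated to 3 channels."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:  # 16-bit gray input
        arr = (arr.astype(np.float64) / arr.max() * 255).astype(np.uint8) \
            if arr.max() > 0 else arr.astype(np.uint8)
    return RawImage(pixels=arr, source_id=path.stem)


def write_raw(img: RawImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        iio.imwrite(path, img.pixels)


def iter_raw_dir(directory) -> list:
    files = sorted(p for p in Path(directory).iterdir()
                   if p.suffix.lower() in _RAW_EXTS)
    return [read_raw(p) for p in files]


def write_preprocessed(pre: PreprocessedImage, out_dir) -> None:
    """16-bit gray TIFF + 8-bit mask PNG + JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = pre.source_id or "image"
    tifffile.imwrite(out_dir / f"{stem}_gray.tif", pre.gray.astype(np.uint16))
    iio.imwrite(out_dir / f"{stem}_mask.png",
                (pre.mask.astype(np.uint8) * 255))
    meta = {"otsu_threshold": pre.otsu_threshold,
            "removed_objects": pre.removed_objects, "flags": pre.flags}
    (out_dir / f"{stem}_meta.json").write_text(json.dumps(meta))


def read_preprocessed(out_dir, stem) -> PreprocessedImage:
    out_dir = Path(out_dir)
    gray = tifffile.imread(out_dir / f"{stem}_gray.tif").astype(np.float64)
    mask = iio.imread(out_dir / f"{stem}_mask.png") > 0
    meta = json.loads((out_dir / f"{stem}_meta.json").read_text())
    return PreprocessedImage(gray=gray, mask=mask,
                             otsu_threshold=meta["otsu_threshold"],
                             removed_objects=meta["removed_objects"],
                             source_id=stem, flags=meta.get("flags", []))
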