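"""Frequency-domain features: Gabor bank, wavelet sub-band energies (Haar and
Daubechies-4), Fourier spectral bands, generic Fourier descriptors of the
silhouette, a granularity spectrum and an SLF-style summary set.

The 2-D discrete wavelet transform is implemented directly with periodized
orthonormal filter banks, so the sum of sub-band energies conserves image
energy exactly (Parseval).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as _ndi
from skimage import measure
from skimage.filters import gabor
from skimage.morphology import disk, opening

__all__ = [
    "wavelet_energies",
    "gabor_features",
    "fourier_band_features",
    "generic_fourier_descriptors",
    "granularity_spectrum",
    "slf_summary",
    "frequency_features",
]

_SQRT2 = math.sqrt(2.0)
_WAVELET_LO = {
    "haar": np.array([1.0, 1.0]) / _SQRT2,
    "db4": np.array([1 + math.sqrt(3), 3 + math.sqrt(3),
                     3 - math.sqrt(3), 1 - math.sqrt(3)]) / (4 * _SQRT2),
}
_STRUCT8 = np.ones((3, 3), dtype=int)


def _highpass(lo: np.ndarray) -> np.ndarray:
    # quadrature mirror filter of an orthonormal lowpass
    g = lo[::-1].copy()
    g[1::2] *= -1.0
    return g


def _dwt_axis(a: np.ndarray, lo: np.ndarray, hi: np.ndarray, axis: int):
    """One periodized analysis step along ``axis`` (length must be even)."""
    a = np.moveaxis(a, axis, -1)
    n = a.shape[-1]
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(len(lo))[None, :]) % n
    taken = a[..., idx]  # (..., n//2, taps)
    ca = taken @ lo
    cd = taken @ hi
    return np.moveaxis(ca, -1, axis), np.moveaxis(cd, -1, axis)


def dwt2(image: np.ndarray, wavelet: str = "haar"):
    """Single-level 2-D DWT with periodization; returns (LL, LH, HL, HH)."""
    lo = _WAVELET_LO[wavelet]
    hi = _highpass(lo)
    a = np.asarray(image, dtype=np.float64)
    la, ha = _dwt_axis(a, lo, hi, axis=0)
    ll, lh = _dwt_axis(la, lo, hi, axis=1)
    hl, hh = _dwt_axis(ha, lo, hi, axis=1)
    return ll, lh, hl, hh


def wavelet_energies(image: np.ndarray, wavelet: str = "haar",
                     levels: int = 3) -> dict[str, float]:
    """Sub-band energies of a ``levels``-deep wavelet decomposition.

    The image is cropped to dimensions divisible by ``2**levels``.  The sum
    of all returned energies equals the energy of the cropped image.
    """
    img = np.asarray(image, dtype=np.float64)
    step = 2**levels
    h = (img.shape[0] // step) * step
    w = (img.shape[1] // step) * step
    if h < step or w < step:
        raise ValueError(f"image {img.shape} smaller than wavelet support for {levels} levels")
    img = img[:h, :w]
    out: dict[str, float] = {}
    ll = img
    for lev in range(1, levels + 1):
        ll, lh, hl, hh = dwt2(ll, wavelet)
        out[f"Wavelet {wavelet} L{lev} LH"] = float((lh**2).sum())
        out[f"Wavelet {wavelet} L{lev} HL"] = float((hl**2).sum())
        out[f"Wavelet {wavelet} L{lev} HH"] = float((hh**2).sum())
    out[f"Wavelet {wavelet} L{levels} LL"] = float((ll**2).sum())
    return out


def gabor_features(gray: np.ndarray, frequencies=(0.1, 0.2, 0.3),
                   n_orientations: int = 4) -> dict[str, float]:
    """Mean filter-response energy per (frequency, orientation) channel,
    normalized by the mean image power."""
    g = np.asarray(gray, dtype=np.float64)
    power = (g**2).mean()
    out: dict[str, float] = {}
    for fi, f in enumerate(frequencies):
        for oi in range(n_orientations):
            theta = oi * math.pi / n_orientations
            if power == 0:
                out[f"Gabor ({fi}, {oi})"] = 0.0
                continue
            real, imag = gabor(g, frequency=f, theta=theta)
            out[f"Gabor ({fi}, {oi})"] = float((real**2 + imag**2).mean() / power)
    return out


def fourier_band_features(gray: np.ndarray, n_bands: int = 8) -> dict[str, float]:
    """Fraction of (non-DC) spectral power per radial frequency band."""
    g = np.asarray(gray, dtype=np.float64)
    spec = np.abs(np.fft.fftshift(np.fft.fft2(g))) ** 2
    h, w = g.shape
    yy, xx = np.indices((h, w))
    r = np.hypot((yy - h // 2) / (h / 2.0), (xx - w // 2) / (w / 2.0)) / math.sqrt(2.0)
    spec[h // 2, w // 2] = 0.0  # drop DC
    total = spec.sum()
    rbin = np.minimum((r * n_bands).astype(int), n_bands - 1)
    out = {}
    for k in range(n_bands):
        e = float(spec[rbin == k].sum())
        out[f"Fourier band ({k})"] = e / total if total > 0 else 0.0
    return out


def generic_fourier_descriptors(mask: np.ndarray, n_rad: int = 4,
                                n_ang: int = 6) -> dict[str, float]:
    """Polar Fourier transform magnitudes of the silhouette, normalized by the
    DC term (so GFD(0,0) == 1 for any non-empty mask)."""
    m = np.asarray(mask, dtype=np.float64)
    out = {f"GFD ({p}, {q})": 0.0 for p in range(n_rad) for q in range(n_ang)}
    if m.sum() == 0:
        return out
    ys, xs = np.nonzero(m)
    yc, xc = ys.mean(), xs.mean()
    r = np.hypot(xs - xc, ys - yc)
    rmax = r.max() or 1.0
    rn = r / rmax
    theta = np.arctan2(ys - yc, xs - xc)
    dc = None
    for p in range(n_rad):
        for q in range(n_ang):
            val = abs(np.exp(-2j * math.pi * rn * p - 1j * q * theta).sum())
            if p == 0 and q == 0:
                dc = val or 1.0
            out[f"GFD ({p}, {q})"] = float(val / dc)
    return out


def granularity_spectrum(gray: np.ndarray, radii=(1, 2, 3, 5, 7)) -> dict[str, float]:
    """Fraction of total intensity removed by successive morphological openings."""
    g = np.asarray(gray, dtype=np.float64)
    total = g.sum()
    out: dict[str, float] = {}
    prev = total
    for k, rad in enumerate(radii):
        if total == 0:
            out[f"Granularity ({k})"] = 0.0
            continue
        opened = opening(g, disk(rad)).sum()
        out[f"Granularity ({k})"] = float((prev - opened) / total)
        prev = opened
    return out


def slf_summary(gray: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """SLF-style whole-image summary: object count/size statistics, distances
    of object centroids to the fluorescence centre, and Euler number."""
    g = np.asarray(gray, dtype=np.float64)
    m = np.asarray(mask, dtype=bool)
    keys = ["SLF object count", "SLF mean object area", "SLF sd object area",
            "SLF largest object fraction", "SLF mean object distance",
            "SLF max object distance", "SLF euler number", "SLF foreground fraction"]
    if not m.any():
        return {k: 0.0 for k in keys}
    labels, num = _ndi.label(m, structure=_STRUCT8)
    props = measure.regionprops(labels)
    areas = np.array([p.area for p in props], dtype=np.float64)
    total = g[m].sum()
    ys, xs = np.nonzero(m)
    w = g[ys, xs]
    wsum = w.sum() or 1.0
    yc = (ys * w).sum() / wsum
    xc = (xs * w).sum() / wsum
    dists = np.array([math.hypot(p.centroid[1] - xc, p.centroid[0] - yc) for p in props])
    diag = math.hypot(*m.shape) or 1.0
    return {
        "SLF object count": float(num),
        "SLF mean object area": float(areas.mean()),
        "SLF sd object area": float(areas.std()),
        "SLF largest object fraction": float(areas.max() / areas.sum()),
        "SLF mean object distance": float(dists.mean() / diag),
        "SLF max object distance": float(dists.max() / diag),
        "SLF euler number": float(measure.euler_number(m, connectivity=2)),
        "SLF foreground fraction": float(m.mean()),
    }


def frequency_features(gray: np.ndarray, mask: np.ndarray,
                       wavelet_levels: int = 3,
                       gabor_frequencies=(0.1, 0.2, 0.3),
                       n_fourier_bands: int = 8,
                       gfd_rad: int = 4, gfd_ang: int = 6,
                       granularity_radii=(1, 2, 3, 5, 7)) -> dict[str, float]:
    """All frequency-class descriptors of a preprocessed gray/mask pair."""
    out: dict[str, float] = {}
    out.update(slf_summary(gray, mask))
    out.update(generic_fourier_descriptors(mask, gfd_rad, gfd_ang))
    out.update(granularity_spectrum(gray, granularity_radii))
    out.update(gabor_features(gray, gabor_frequencies))
    for wavelet in ("db4", "haar"):
        out.update(wavelet_energies(gray, wavelet, wavelet_levels))
    out.update(fourier_band_features(gray, n_fourier_bands))
    return out
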