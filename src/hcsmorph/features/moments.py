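"""Orthogonal-moment image descriptors.

Implements geometric moments (raw, and translation/scale-normalized central
moments), separable Cartesian families (Legendre, discrete Tchebichef,
weighted Krawtchouk) and polar families on the unit disc (Zernike,
pseudo-Zernike, radial Tchebichef-Fourier, Fourier-Mellin).

Coordinate convention: ``x`` is the column index and ``y`` the row index,
both 0-based; an image of shape ``(Ny, Nx)`` spans ``x in [0, Nx)`` and
``y in [0, Ny)``.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.special import eval_legendre, gammaln

__all__ = [
    "geometric_moment",
    "geometric_moments",
    "legendre_moments",
    "tchebichef_moments",
    "krawtchouk_moments",
    "zernike_moments",
    "pseudo_zernike_moments",
    "radial_tchebichef_fourier_moments",
    "fourier_mellin_moments",
    "moment_family",
    "MOMENT_FAMILIES",
]

_MAX_STABLE_ORDER = 25


def _check_order(order: int) -> None:
    if order < 0:
        raise ValueError("moment order must be >= 0")
    if order > _MAX_STABLE_ORDER:
        raise ValueError(
            f"order {order} beyond numeric stability; safe bound is {_MAX_STABLE_ORDER}"
        )


# ---------------------------------------------------------------------------
# geometric moments
# ---------------------------------------------------------------------------

def geometric_moment(image: np.ndarray, i: int, j: int, normalized: bool = False) -> float:
    """Geometric moment ``M_ij = sum_x sum_y x^i y^j I(x, y)``.

    In normalized mode the fluorescence centroid is translated to the origin
    (translation normalization) and the central moment is divided by
    ``M00**((i + j + 2) / 2)`` (scale normalization relating to the total
    number of fluorescence pixels).  An empty image returns 0.
    """
    _check_order(i)
    _check_order(j)
    img = np.asarray(image, dtype=np.float64)
    if i < j:
        # canonical orientation: makes the axis-exchange symmetry
        # M_ij(image) == M_ji(image.T) hold bitwise, not just numerically
        img, i, j = img.T, j, i
    ny, nx = img.shape
    x = np.arange(nx, dtype=np.float64)
    y = np.arange(ny, dtype=np.float64)
    if not normalized:
        return float(y**j @ img @ x**i)
    m00 = img.sum()
    if m00 <= 0:
        return 0.0
    xc = float(img.sum(axis=0) @ x) / m00
    yc = float(img.sum(axis=1) @ y) / m00
    mu = float((y - yc) ** j @ img @ (x - xc) ** i)
    return mu / m00 ** ((i + j + 2) / 2.0)


def geometric_moments(image: np.ndarray, max_order: int = 3,
                      normalized: bool = True) -> dict[tuple[int, int], float]:
    """All moments with total order ``i + j <= max_order``."""
    out: dict[tuple[int, int], float] = {}
    for i in range(max_order + 1):
        for j in range(max_order + 1 - i):
            out[(i, j)] = geometric_moment(image, i, j, normalized=normalized)
    return out


# ---------------------------------------------------------------------------
# separable Cartesian families
# ---------------------------------------------------------------------------

def _legendre_basis(n_points: int, max_order: int) -> np.ndarray:
    # pixel centers mapped onto [-1, 1]
    t = -1.0 + 2.0 * np.arange(n_points) / (n_points - 1)
    return np.stack([eval_legendre(p, t) for p in range(max_order + 1)])


@lru_cache(maxsize=32)
def _tchebichef_basis(n_points: int, max_order: int) -> np.ndarray:
    """Orthonormal discrete Tchebichef polynomials on {0..N-1} (rows = order)."""
    N = n_points
    x = np.arange(N, dtype=np.float64)
    T = np.zeros((max_order + 1, N))
    T[0] = 1.0 / math.sqrt(N)
    if max_order >= 1:
        T[1] = (2 * x + 1 - N) * math.sqrt(3.0 / (N * (N**2 - 1)))
    for n in range(2, max_order + 1):
        a1 = (2.0 / n) * math.sqrt((4 * n**2 - 1.0) / (N**2 - n**2))
        a2 = ((1.0 - N) / n) * math.sqrt((4 * n**2 - 1.0) / (N**2 - n**2))
        a3 = ((n - 1.0) / n) * math.sqrt((2 * n + 1.0) / (2 * n - 3.0)) \
            * math.sqrt((N**2 - (n - 1) ** 2) / (N**2 - n**2))
        T[n] = (a1 * x + a2) * T[n - 1] - a3 * T[n - 2]
    return T


@lru_cache(maxsize=32)
def _krawtchouk_basis(n_points: int, max_order: int, p: float = 0.5) -> np.ndarray:
    """Weighted orthonormal Krawtchouk functions on {0..N-1} (rows = order)."""
    N = n_points
    Np = N - 1
    x = np.arange(N, dtype=np.float64)
    K = np.zeros((max_order + 1, N))
    K[0] = 1.0
    if max_order >= 1:
        K[1] = 1.0 - x / (p * Np)
    for n in range(1, max_order):
        K[n + 1] = ((Np * p - 2 * n * p + n - x) * K[n] - n * (1 - p) * K[n - 1]) \
            / (p * (Np - n))
    logw = (gammaln(Np + 1) - gammaln(x + 1) - gammaln(Np - x + 1)
            + x * math.log(p) + (Np - x) * math.log1p(-p))
    sqrt_w = np.exp(0.5 * logw)
    out = np.empty_like(K)
    for n in range(max_order + 1):
        logrho = n * math.log((1 - p) / p) \
            - (gammaln(Np + 1) - gammaln(n + 1) - gammaln(Np - n + 1))
        out[n] = K[n] * sqrt_w * math.exp(-0.5 * logrho)
    return out


def _separable_moments(image: np.ndarray, bx: np.ndarray, by: np.ndarray,
                       scale: np.ndarray | None = None) -> dict[tuple[int, int], float]:
    img = np.asarray(image, dtype=np.float64)
    M = by @ img @ bx.T  # M[q, p] = sum_y sum_x by_q(y) bx_p(x) I
    if scale is not None:
        M = M * scale
    return {(p, q): float(M[q, p]) for p in range(bx.shape[0]) for q in range(by.shape[0])}


def legendre_moments(image: np.ndarray, max_order: int = 8) -> dict[tuple[int, int], float]:
    """Legendre moments ``L_pq`` over the canonical ``[-1, 1]^2`` domain.

    ``L_pq = (2p+1)(2q+1)/(Nx*Ny) * sum P_p(x') P_q(y') I``; keys are
    ``(p, q)`` with ``p`` the x-order.
    """
    _check_order(max_order)
    ny, nx = np.asarray(image).shape
    bx = _legendre_basis(nx, max_order)
    by = _legendre_basis(ny, max_order)
    orders = np.arange(max_order + 1)
    scale = np.outer(2 * orders + 1, 2 * orders + 1) / (nx * ny)  # [q, p]
    return _separable_moments(image, bx, by, scale)


def tchebichef_moments(image: np.ndarray, max_order: int = 8) -> dict[tuple[int, int], float]:
    """Discrete Tchebichef moments with orthonormal polynomials."""
    _check_order(max_order)
    ny, nx = np.asarray(image).shape
    return _separable_moments(image, _tchebichef_basis(nx, max_order),
                              _tchebichef_basis(ny, max_order))


def krawtchouk_moments(image: np.ndarray, max_order: int = 8,
                       p: float = 0.5) -> dict[tuple[int, int], float]:
    """Weighted Krawtchouk moments (weight parameter ``p`` on both axes)."""
    _check_order(max_order)
    ny, nx = np.asarray(image).shape
    return _separable_moments(image, _krawtchouk_basis(nx, max_order, p),
                              _krawtchouk_basis(ny, max_order, p))


# ---------------------------------------------------------------------------
# polar families on the unit disc
# ---------------------------------------------------------------------------

def _disc_coordinates(image: np.ndarray, radius_policy: str = "bbox_inscribed"):
    """Map foreground pixels into the unit disc about the intensity centroid.

    Returns ``(values, rho, theta)`` for pixels with ``rho <= 1``; ``None``
    for an empty image.  ``radius_policy`` is ``"bbox_inscribed"`` (half the
    smaller bounding-box side of the support) or ``"circumscribed"``.
    """
    img = np.asarray(image, dtype=np.float64)
    total = img.sum()
    if total <= 0:
        return None
    ys, xs = np.nonzero(img)
    vals = img[ys, xs]
    xc = (xs * vals).sum() / total
    yc = (ys * vals).sum() / total
    dx = xs - xc
    dy = ys - yc
    if radius_policy == "circumscribed":
        radius = float(np.hypot(dx, dy).max())
    elif radius_policy == "bbox_inscribed":
        radius = 0.5 * min(xs.max() - xs.min() + 1, ys.max() - ys.min() + 1)
    else:
        raise ValueError(f"unknown radius policy {radius_policy!r}")
    if radius <= 0:
        radius = 1.0
    rho = np.hypot(dx, dy) / radius
    inside = rho <= 1.0
    if not inside.any():
        return None
    theta = np.arctan2(dy[inside], dx[inside])
    return vals[inside], rho[inside], theta


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s) * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)))
        out += c * rho ** (n - 2 * s)
    return out


def _pseudo_zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range(n - m + 1):
        c = ((-1) ** s * math.factorial(2 * n + 1 - s)
             / (math.factorial(s) * math.factorial(n - m - s)
                * math.factorial(n + m + 1 - s)))
        out += c * rho ** (n - s)
    return out


def zernike_moments(image: np.ndarray, max_order: int = 8,
                    radius_policy: str = "bbox_inscribed") -> dict[tuple[int, int], float]:
    """Zernike moment magnitudes ``|Z_nm|`` for ``n <= max_order``, ``m >= 0``.

    The image support is mapped into the unit disc centred on the intensity
    centroid; intensities are normalized by their in-disc sum so the result
    is invariant to uniform intensity scaling, and magnitudes are reported
    for rotation invariance.
    """
    _check_order(max_order)
    coords = _disc_coordinates(image, radius_policy)
    out: dict[tuple[int, int], float] = {}
    for n in range(max_order + 1):
        for m in range(n % 2, n + 1, 2):
            out[(n, m)] = 0.0
    if coords is None:
        return out
    vals, rho, theta = coords
    vals = vals / vals.sum()
    for (n, m) in out:
        kernel = _zernike_radial(n, m, rho) * np.exp(-1j * m * theta)
        out[(n, m)] = float(abs((n + 1) / math.pi * (vals * kernel).sum()))
    return out


def pseudo_zernike_moments(image: np.ndarray, max_order: int = 6,
                           radius_policy: str = "bbox_inscribed") -> dict[tuple[int, int], float]:
    """Pseudo-Zernike moment magnitudes for ``n <= max_order``, ``0 <= m <= n``."""
    _check_order(max_order)
    coords = _disc_coordinates(image, radius_policy)
    out = {(n, m): 0.0 for n in range(max_order + 1) for m in range(n + 1)}
    if coords is None:
        return out
    vals, rho, theta = coords
    vals = vals / vals.sum()
    for (n, m) in out:
        kernel = _pseudo_zernike_radial(n, m, rho) * np.exp(-1j * m * theta)
        out[(n, m)] = float(abs((n + 1) / math.pi * (vals * kernel).sum()))
    return out


def radial_tchebichef_fourier_moments(image: np.ndarray, max_rad: int = 5,
                                      max_ang: int = 5, n_bins: int = 32,
                                      radius_policy: str = "bbox_inscribed"
                                      ) -> dict[tuple[int, int], float]:
    """Radial Tchebichef-Fourier moment magnitudes.

    The radial coordinate is quantized into ``n_bins`` annuli carrying
    orthonormal discrete Tchebichef polynomials; the angular kernel is the
    Fourier factor ``exp(-i m theta)``.
    """
    _check_order(max_rad)
    coords = _disc_coordinates(image, radius_policy)
    out = {(p, m): 0.0 for p in range(max_rad + 1) for m in range(max_ang + 1)}
    if coords is None:
        return out
    vals, rho, theta = coords
    vals = vals / vals.sum()
    rbin = np.minimum((rho * n_bins).astype(int), n_bins - 1)
    basis = _tchebichef_basis(n_bins, max_rad)
    for (p, m) in out:
        kernel = basis[p][rbin] * np.exp(-1j * m * theta)
        out[(p, m)] = float(abs((vals * kernel).sum()))
    return out


def fourier_mellin_moments(image: np.ndarray, max_s: int = 4, max_ang: int = 4,
                           radius_policy: str = "bbox_inscribed") -> dict[tuple[int, int], float]:
    """Fourier-Mellin moment magnitudes ``|sum I rho^s exp(-i m theta)|``."""
    _check_order(max_s)
    coords = _disc_coordinates(image, radius_policy)
    out = {(s, m): 0.0 for s in range(max_s + 1) for m in range(max_ang + 1)}
    if coords is None:
        return out
    vals, rho, theta = coords
    vals = vals / vals.sum()
    for (s, m) in out:
        kernel = rho**s * np.exp(-1j * m * theta)
        out[(s, m)] = float(abs((vals * kernel).sum()))
    return out


MOMENT_FAMILIES = {
    "geometric": geometric_moments,
    "legendre": legendre_moments,
    "tchebichef": tchebichef_moments,
    "krawtchouk": krawtchouk_moments,
    "zernike": zernike_moments,
    "pseudo_zernike": pseudo_zernike_moments,
    "radial_tchebichef_fourier": radial_tchebichef_fourier_moments,
    "fourier_mellin": fourier_mellin_moments,
}


def moment_family(image: np.ndarray, family: str, max_order: int | None = None,
                  **kwargs) -> dict[tuple[int, int], float]:
    """Dispatch to one moment family by name; keys are ``(order_x/ radial, order_y/ angular)``."""
    if family not in MOMENT_FAMILIES:
        raise ValueError(f"unknown moment family {family!r}")
    fn = MOMENT_FAMILIES[family]
    if max_order is None:
        return fn(image, **kwargs)
    if family == "radial_tchebichef_fourier":
        return fn(image, max_rad=max_order, **kwargs)
    if family == "fourier_mellin":
        return fn(image, max_s=max_order, **kwargs)
    return fn(image, max_order=max_order, **kwargs)
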