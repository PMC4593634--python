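"""Oracle tests for every moment family: each implementation is compared to
an independently coded brute-force double sum over explicitly constructed
polynomial/kernel tables on small random images."""

import math

import numpy as np
import pytest

from hcsmorph.features.moments import (fourier_mellin_moments,
                                       geometric_moment, geometric_moments,
                                       krawtchouk_moments, legendre_moments,
                                       pseudo_zernike_moments,
                                       radial_tchebichef_fourier_moments,
                                       tchebichef_moments, zernike_moments,
                                       _disc_coordinates, _tchebichef_basis,
                                       _krawtchouk_basis)

RTOL = 1e-8


def random_images(rng, n=5, size=16):
    return [rng.random((size, size)) for _ in range(n)]


# ---------------------------------------------------------------------------
# geometric moments
# ---------------------------------------------------------------------------

class TestGeometric:
    def test_zero_image(self):
        img = np.zeros((6, 6))
        for i in range(3):
            for j in range(3):
                assert geometric_moment(img, i, j) == 0.0
                assert geometric_moment(img, i, j, normalized=True) == 0.0

    def test_two_point_mass(self):
        img = np.zeros((5, 5))
        img[1, 1] = 1.0  # (x=1, y=1)
        img[3, 3] = 1.0
        assert geometric_moment(img, 0, 0) == 2.0
        assert geometric_moment(img, 1, 1) == 1 * 1 + 3 * 3

    def test_raw_matches_double_loop(self, rng):
        img = rng.random((7, 9))
        for i in range(3):
            for j in range(3):
                expected = sum(x**i * y**j * img[y, x]
                               for y in range(7) for x in range(9))
                assert geometric_moment(img, i, j) == pytest.approx(expected, rel=1e-12)

    def test_transpose_symmetry_exact(self, rng):
        img = rng.random((8, 8))
        assert geometric_moment(img, 0, 2, normalized=True) == \
            geometric_moment(img.T, 2, 0, normalized=True)

    def test_translation_invariance(self, rng):
        img = np.zeros((40, 40))
        img[5:12, 6:15] = rng.random((7, 9))
        shifted = np.roll(img, (11, 9), axis=(0, 1))
        for (i, j) in [(0, 2), (2, 0), (1, 1), (2, 2)]:
            a = geometric_moment(img, i, j, normalized=True)
            b = geometric_moment(shifted, i, j, normalized=True)
            assert a == pytest.approx(b, rel=1e-6, abs=1e-12)

    def test_scale_invariance_silhouette(self):
        img = np.zeros((50, 50))
        img[10:18, 12:22] = 1.0
        big = np.kron(img, np.ones((2, 2)))  # exact 2x rescale
        for (i, j) in [(0, 2), (2, 0), (2, 2)]:
            a = geometric_moment(img, i, j, normalized=True)
            b = geometric_moment(big, i, j, normalized=True)
            assert b == pytest.approx(a, rel=0.02)  # discrete rescale is approximate

    def test_dispersion_monotonic(self):
        # two equal point masses moved symmetrically farther from center in y
        def m02(sep):
            img = np.zeros((41, 41))
            img[20 - sep, 20] = 1.0
            img[20 + sep, 20] = 1.0
            return geometric_moment(img, 0, 2, normalized=True)

        values = [m02(s) for s in (2, 5, 9, 15)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_centered_point_mass_zero(self):
        img = np.zeros((9, 9))
        img[4, 4] = 5.0
        assert geometric_moment(img, 0, 2, normalized=True) == 0.0

    def test_order_counts(self):
        out = geometric_moments(np.ones((4, 4)), max_order=3)
        assert len(out) == 10  # (i, j) with i + j <= 3


# ---------------------------------------------------------------------------
# Legendre
# ---------------------------------------------------------------------------

def legendre_poly_table(order, n):
    """Legendre values by the numpy.polynomial module (independent code path)."""
    t = -1.0 + 2.0 * np.arange(n) / (n - 1)
    table = []
    for p in range(order + 1):
        coeffs = np.zeros(p + 1)
        coeffs[p] = 1.0
        table.append(np.polynomial.legendre.legval(t, coeffs))
    return np.array(table)


class TestLegendre:
    def test_constant_image_zeroth(self):
        out = legendre_moments(np.ones((10, 12)), max_order=2)
        assert out[(0, 0)] == pytest.approx(1.0, rel=1e-12)

    def test_matches_double_sum_oracle(self, rng):
        for img in random_images(rng, n=5):
            out = legendre_moments(img, max_order=4)
            P = legendre_poly_table(4, 16)
            for p in range(5):
                for q in range(5):
                    lam = (2 * p + 1) * (2 * q + 1) / (16 * 16)
                    expected = lam * sum(P[p, x] * P[q, y] * img[y, x]
                                         for y in range(16) for x in range(16))
                    assert out[(p, q)] == pytest.approx(expected, rel=RTOL, abs=1e-12)


# ---------------------------------------------------------------------------
# Tchebichef (discrete)
# ---------------------------------------------------------------------------

def gram_schmidt_basis(n, order, weight=None):
    """Orthonormalized monomials on {0..n-1} -- a recurrence-free oracle."""
    x = np.arange(n, dtype=np.float64)
    w = np.ones(n) if weight is None else weight
    vecs = [x**k * np.sqrt(w) for k in range(order + 1)]
    basis = []
    for v in vecs:
        for b in basis:
            v = v - (v @ b) * b
        basis.append(v / np.linalg.norm(v))
    return np.array(basis)


class TestTchebichef:
    def test_basis_orthonormal(self):
        T = _tchebichef_basis(16, 6)
        assert np.abs(T @ T.T - np.eye(7)).max() < 1e-12

    def test_basis_matches_gram_schmidt(self):
        T = _tchebichef_basis(16, 5)
        G = gram_schmidt_basis(16, 5)
        # Gram-Schmidt fixes each vector up to sign
        assert np.abs(np.abs(T) - np.abs(G)).max() < 1e-9

    def test_matches_double_sum_oracle(self, rng):
        G = gram_schmidt_basis(16, 4)
        for img in random_images(rng, n=5):
            out = tchebichef_moments(img, max_order=4)
            for p in range(5):
                for q in range(5):
                    expected = sum(G[p, x] * G[q, y] * img[y, x]
                                   for y in range(16) for x in range(16))
                    assert abs(out[(p, q)]) == pytest.approx(abs(expected),
                                                             rel=RTOL, abs=1e-12)


# ---------------------------------------------------------------------------
# Krawtchouk (weighted)
# ---------------------------------------------------------------------------

class TestKrawtchouk:
    def test_basis_orthonormal(self):
        K = _krawtchouk_basis(16, 6, 0.5)
        assert np.abs(K @ K.T - np.eye(7)).max() < 1e-10

    def test_basis_matches_weighted_gram_schmidt(self):
        from scipy.special import comb
        n = 16
        x = np.arange(n)
        w = comb(n - 1, x) * 0.5 ** (n - 1)
        K = _krawtchouk_basis(n, 5, 0.5)
        G = gram_schmidt_basis(n, 5, weight=w)
        assert np.abs(np.abs(K) - np.abs(G)).max() < 1e-9

    def test_matches_double_sum_oracle(self, rng):
        from scipy.special import comb
        n = 16
        w = comb(n - 1, np.arange(n)) * 0.5 ** (n - 1)
        G = gram_schmidt_basis(n, 4, weight=w)
        for img in random_images(rng, n=5):
            out = krawtchouk_moments(img, max_order=4)
            for p in range(5):
                for q in range(5):
                    expected = sum(G[p, x] * G[q, y] * img[y, x]
                                   for y in range(n) for x in range(n))
                    assert abs(out[(p, q)]) == pytest.approx(abs(expected),
                                                             rel=RTOL, abs=1e-12)


# ---------------------------------------------------------------------------
# polar families
# ---------------------------------------------------------------------------

def zernike_radial_oracle(n, m, rho):
    total = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        num = (-1) ** s * math.factorial(n - s)
        den = (math.factorial(s) * math.factorial((n + m) // 2 - s)
               * math.factorial((n - m) // 2 - s))
        total = total + (num / den) * rho ** (n - 2 * s)
    return total


class TestPolarFamilies:
    def test_disc_rotational_symmetry(self, disc_image):
        # a rasterized disc keeps only 4-fold symmetry, so harmonics with
        # m % 4 != 0 vanish exactly while m = 4, 8, ... carry tiny
        # pixelation residue
        out = zernike_moments(disc_image, max_order=6)
        for (n, m), v in out.items():
            if m == 0:
                continue
            if m % 4 != 0:
                assert v < 1e-10, (n, m, v)
            else:
                assert v < 0.05, (n, m, v)

    def test_pseudo_zernike_disc_symmetry(self, disc_image):
        out = pseudo_zernike_moments(disc_image, max_order=4)
        for (n, m), v in out.items():
            if m == 0:
                continue
            if m % 4 != 0:
                assert v < 1e-10
            else:
                assert v < 0.05

    def test_zernike_matches_double_loop(self, rng):
        for img in random_images(rng, n=3):
            out = zernike_moments(img, max_order=5)
            vals, rho, theta = _disc_coordinates(img, "bbox_inscribed")
            vals = vals / vals.sum()
            for (n, m), got in out.items():
                acc = 0.0 + 0.0j
                for v, r, t in zip(vals, rho, theta):
                    acc += v * zernike_radial_oracle(n, m, np.array([r]))[0] \
                        * np.exp(-1j * m * t)
                expected = abs((n + 1) / math.pi * acc)
                assert got == pytest.approx(expected, rel=1e-8, abs=1e-12)

    def test_fourier_mellin_matches_double_loop(self, rng):
        img = rng.random((16, 16))
        out = fourier_mellin_moments(img, max_s=3, max_ang=3)
        vals, rho, theta = _disc_coordinates(img, "bbox_inscribed")
        vals = vals / vals.sum()
        for (s, m), got in out.items():
            acc = sum(v * r**s * np.exp(-1j * m * t)
                      for v, r, t in zip(vals, rho, theta))
            assert got == pytest.approx(abs(acc), rel=1e-8, abs=1e-12)

    def test_rtf_matches_double_loop(self, rng):
        img = rng.random((16, 16))
        out = radial_tchebichef_fourier_moments(img, max_rad=3, max_ang=3, n_bins=8)
        vals, rho, theta = _disc_coordinates(img, "bbox_inscribed")
        vals = vals / vals.sum()
        T = _tchebichef_basis(8, 3)
        rbin = np.minimum((rho * 8).astype(int), 7)
        for (p, m), got in out.items():
            acc = sum(v * T[p, rb] * np.exp(-1j * m * t)
                      for v, rb, t in zip(vals, rbin, theta))
            assert got == pytest.approx(abs(acc), rel=1e-8, abs=1e-12)

    def test_empty_image_all_zero(self):
        img = np.zeros((10, 10))
        for fn in (zernike_moments, pseudo_zernike_moments,
                   radial_tchebichef_fourier_moments, fourier_mellin_moments):
            assert all(v == 0.0 for v in fn(img).values())

    def test_order_beyond_stability_rejected(self):
        with pytest.raises(ValueError, match="safe bound"):
            zernike_moments(np.ones((8, 8)), max_order=40)
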