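import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hcsmorph.preprocess import (PreprocessConfig, RawImage, binarize_otsu,
                                 downsample, normalize_intensity, preprocess,
                                 remove_small_objects, to_grayscale,
                                 LUMA_WEIGHTS, OTSU_BINS, INTENSITY_MAX)


def rgb(r, g, b, shape=(4, 4)):
    px = np.zeros(shape + (3,), dtype=np.uint8)
    px[..., 0], px[..., 1], px[..., 2] = r, g, b
    return RawImage(pixels=px)


# ---------------------------------------------------------------------------
# to_grayscale
# ---------------------------------------------------------------------------

class TestToGrayscale:
    def test_green_channel_identity(self):
        out = to_grayscale(rgb(0, 255, 0), mode="green")
        assert (out == 255).all()

    def test_all_black(self):
        assert (to_grayscale(rgb(0, 0, 0)) == 0).all()

    def test_luminance_matches_scalar_oracle(self, rng):
        px = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
        out = to_grayscale(RawImage(pixels=px))
        for y in range(8):
            for x in range(8):
                expected = sum(w * float(px[y, x, k]) for k, w in enumerate(LUMA_WEIGHTS))
                assert out[y, x] == pytest.approx(expected, abs=1e-9)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            RawImage(pixels=np.zeros((1, 5, 3), dtype=np.uint8))


# ---------------------------------------------------------------------------
# normalize_intensity
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_three_levels(self):
        out = normalize_intensity(np.array([[0.0, 128.0], [255.0, 0.0]]))
        assert out[0, 0] == 0
        assert out[0, 1] == 32896  # 128 * 257 exactly
        assert out[1, 0] == 65535

    def test_constant_maps_to_zero(self):
        assert (normalize_intensity(np.full((3, 3), 42.0)) == 0).all()

    def test_full_range_unchanged(self, random_gray):
        assert np.array_equal(normalize_intensity(random_gray), random_gray)

    @given(arrays(np.float64, (5, 5), elements=st.floats(0, 255)))
    @settings(max_examples=50, deadline=None)
    def test_range_exact(self, img):
        out = normalize_intensity(img)
        if np.ptp(img) > 0:
            assert out.min() == 0 and out.max() == 65535
        else:
            assert (out == 0).all()


# ---------------------------------------------------------------------------
# downsample
# ---------------------------------------------------------------------------

class TestDownsample:
    def test_single_block_mean(self):
        out = downsample(np.array([[0.0, 0.0], [65535.0, 65535.0]]))
        assert out.shape == (1, 1)
        assert out[0, 0] == 32768  # rint(32767.5), round-half-even

    def test_constant_identity(self):
        out = downsample(np.full((4, 4), 1234.0))
        assert out.shape == (2, 2)
        assert (out == 1234).all()

    def test_matches_double_loop_oracle(self, rng):
        img = rng.integers(0, 65536, size=(16, 16)).astype(np.float64)
        out = downsample(img)
        for i in range(8):
            for j in range(8):
                block = img[2 * i:2 * i + 2, 2 * j:2 * j + 2]
                assert out[i, j] == np.rint(block.mean())

    def test_intensity_conserved(self, rng):
        img = rng.integers(0, 65536, size=(20, 20)).astype(np.float64)
        out = downsample(img)
        # 4x the down-sampled sum equals the original sum within rounding
        assert abs(4 * out.sum() - img.sum()) <= 2 * out.size

    def test_odd_dims_padded(self):
        out = downsample(np.ones((5, 7)))
        assert out.shape == (3, 4)


# ---------------------------------------------------------------------------
# binarize_otsu
# ---------------------------------------------------------------------------

def otsu_oracle(gray):
    """Exhaustive scan of all 256 candidate splits (independent of the
    cumulative-sum implementation)."""
    edges = np.linspace(0.0, float(INTENSITY_MAX), OTSU_BINS + 1)
    hist, _ = np.histogram(gray, bins=edges)
    best_t, best_v = 0, -1.0
    for t in range(OTSU_BINS - 1):
        n0 = hist[:t + 1].sum()
        n1 = hist[t + 1:].sum()
        if n0 == 0 or n1 == 0:
            continue
        bins = np.arange(OTSU_BINS)
        mu0 = (hist[:t + 1] * bins[:t + 1]).sum() / n0
        mu1 = (hist[t + 1:] * bins[t + 1:]).sum() / n1
        v = n0 * n1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsu:
    def test_bimodal(self):
        gray = np.full((10, 10), 2570.0)
        gray[5:] = 51400.0
        mask, thr = binarize_otsu(gray)
        assert 2570 < thr < 51400
        assert mask.sum() == 50
        assert mask[5:].all() and not mask[:5].any()

    def test_matches_exhaustive_oracle(self, rng):
        edges = np.linspace(0.0, float(INTENSITY_MAX), OTSU_BINS + 1)
        for _ in range(20):
            gray = rng.integers(0, 65536, size=(16, 16)).astype(np.float64)
            _, thr = binarize_otsu(gray)
            assert thr == pytest.approx(edges[otsu_oracle(gray) + 1])

    def test_constant_image(self):
        mask, thr = binarize_otsu(np.zeros((5, 5)))
        assert not mask.any()
        assert math.isnan(thr)


# ---------------------------------------------------------------------------
# remove_small_objects
# ---------------------------------------------------------------------------

def flood_fill_areas(mask):
    """8-connected component areas by explicit flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    areas = {}
    label = 0
    for sy in range(mask.shape[0]):
        for sx in range(mask.shape[1]):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            label += 1
            stack = [(sy, sx)]
            seen[sy, sx] = True
            pixels = []
            while stack:
                y, x = stack.pop()
                pixels.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1]
                                and mask[ny, nx] and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            areas[label] = pixels
    return areas


def blob(area, shape=(30, 30), offset=(0, 0)):
    mask = np.zeros(shape, dtype=bool)
    side = int(np.ceil(np.sqrt(area)))
    filled = 0
    for y in range(side):
        for x in range(side):
            if filled == area:
                break
            mask[offset[0] + y, offset[1] + x] = True
            filled += 1
    return mask


class TestRemoveSmallObjects:
    def test_49_px_removed(self):
        assert not remove_small_objects(blob(49), 50).any()

    def test_50_px_kept(self):
        out = remove_small_objects(blob(50), 50)
        assert out.sum() == 50

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            mask = rng.random((24, 24)) < 0.35
            out = remove_small_objects(mask, 6)
            expected = np.zeros_like(mask)
            for pixels in flood_fill_areas(mask).values():
                if len(pixels) >= 6:
                    for y, x in pixels:
                        expected[y, x] = True
            assert np.array_equal(out, expected)

    def test_idempotent_and_monotone(self, rng):
        mask = rng.random((30, 30)) < 0.4
        once = remove_small_objects(mask, 8)
        assert np.array_equal(once, remove_small_objects(once, 8))
        prev_area = mask.sum()
        for size in (2, 5, 10, 20):
            area = remove_small_objects(mask, size).sum()
            assert area <= prev_area
            prev_area = area


# ---------------------------------------------------------------------------
# full preprocess
# ---------------------------------------------------------------------------

def disc_phantom(rng, n_discs=20, radius=6, shape=(240, 320), n_speckles=30):
    """Bright discs on dark noise, plus sub-threshold speckles. Disc centers
    are spaced so components never merge."""
    h, w = shape
    px = rng.integers(0, 20, size=(h, w, 3)).astype(np.uint8)
    centers = []
    grid = [(y, x) for y in range(radius + 2, h - radius - 2, 4 * radius)
            for x in range(radius + 2, w - radius - 2, 4 * radius)]
    idx = rng.choice(len(grid), size=n_discs, replace=False)
    yy, xx = np.indices((h, w))
    for k in idx:
        cy, cx = grid[k]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        px[mask] = (40, 220, 30)
        centers.append((cy, cx))
    for _ in range(n_speckles):
        sy, sx = rng.integers(2, h - 4), rng.integers(2, w - 4)
        if not any(abs(sy - cy) < 2 * radius and abs(sx - cx) < 2 * radius
                   for cy, cx in centers):
            px[sy:sy + 2, sx:sx + 2] = (40, 220, 30)
    return RawImage(pixels=px), len(centers)


class TestPreprocess:
    def test_disc_phantom_components(self, rng):
        raw, n_discs = disc_phantom(rng)
        # a radius-6 disc covers ~113 px at full scale, ~28 px after 2x
        # down-sampling, so use a min size between speckle (<= 4 px) and disc
        pre = preprocess(raw, PreprocessConfig(min_object_size=15))
        from scipy import ndimage
        _, n = ndimage.label(pre.mask, structure=np.ones((3, 3), dtype=int))
        assert pre.gray.shape == (120, 160)
        assert n == n_discs

    def test_all_black(self):
        raw = RawImage(pixels=np.zeros((8, 8, 3), dtype=np.uint8))
        pre = preprocess(raw)
        assert not pre.mask.any()
        assert "constant_image" in pre.flags

    def test_mask_implies_positive_gray(self, rng):
        raw, _ = disc_phantom(rng)
        pre = preprocess(raw, PreprocessConfig(min_object_size=15))
        assert (pre.gray[pre.mask] > 0).all()
        assert (pre.gray[~pre.mask] == 0).all()

    def test_gray_range(self, rng):
        raw, _ = disc_phantom(rng)
        pre = preprocess(raw, PreprocessConfig(min_object_size=15))
        assert pre.gray.min() == 0
        assert pre.gray.max() == 65535

    def test_component_count_stable_under_reprocessing(self, rng):
        raw, n_discs = disc_phantom(rng)
        cfg = PreprocessConfig(min_object_size=15)
        pre = preprocess(raw, cfg)
        # rebuild an RGB image from the preprocessed gray and run again
        up = np.kron(pre.gray / 257.0, np.ones((2, 2)))
        px = np.zeros(up.shape + (3,), dtype=np.uint8)
        px[..., 1] = np.clip(up, 0, 255).astype(np.uint8)
        pre2 = preprocess(RawImage(pixels=px), cfg)
        from scipy import ndimage
        s = np.ones((3, 3), dtype=int)
        assert ndimage.label(pre2.mask, structure=s)[1] == \
            ndimage.label(pre.mask, structure=s)[1]
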