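"""Segmentation operators against independent brute-force oracles.

Each oracle re-derives the operator's documented definition through a
different mechanism (scalar loops or shifted-array stacking) so that a
bit-exact match is a genuine cross-check, not a restatement.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adiposizer import (
    CalibratedImage,
    DegenerateHistogramError,
    SegmentationParams,
    apply_threshold,
    erode,
    remove_outliers,
    segment,
    triangle_threshold,
)
from adiposizer.segmentation import disk_offsets, histogram256

# ---------------------------------------------------------------- oracles


def triangle_oracle(hist, background="dark"):
    """Scalar re-derivation: true perpendicular point-line distance per bin."""
    hist = [float(v) for v in hist]
    nonzero = [i for i in range(256) if hist[i] > 0]
    peak = hist.index(max(hist))
    tail = nonzero[-1] if background == "dark" else nonzero[0]
    if peak == tail:
        return peak
    lo, hi = sorted((peak, tail))
    x1, y1, x2, y2 = peak, hist[peak], tail, hist[tail]
    norm = math.hypot(x2 - x1, y2 - y1)
    best_bin, best_dist = lo, -1.0
    for b in range(lo, hi + 1):
        dist = abs((x2 - x1) * (y1 - hist[b]) - (x1 - b) * (y2 - y1)) / norm
        if dist > best_dist:
            best_bin, best_dist = b, dist
    return best_bin


def erode_oracle(mask):
    """Per-pixel 3×3 minimum via shifted copies over a background-padded frame."""
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    out = np.ones_like(mask)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            out &= padded[1 + dy : padded.shape[0] - 1 + dy, 1 + dx : padded.shape[1] - 1 + dx]
    return out


def remove_outliers_oracle(img, radius, threshold, which="bright"):
    """Sliding-window gather with sentinel padding; lower median by sorting."""
    img = np.asarray(img, dtype=np.int64)
    r = int(np.floor(radius))
    offs = [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    padded = np.pad(img, r, constant_values=10_000)  # sentinel sorts last
    windows = np.stack(
        [padded[r + dy : r + dy + img.shape[0], r + dx : r + dx + img.shape[1]] for dy, dx in offs],
        axis=-1,
    )
    windows = np.sort(windows, axis=-1)
    n_valid = (windows < 10_000).sum(axis=-1)
    med = np.take_along_axis(windows, ((n_valid - 1) // 2)[..., None], axis=-1)[..., 0]
    out = img.copy()
    if which == "bright":
        hit = img - med > threshold
    else:
        hit = med - img > threshold
    out[hit] = med[hit]
    return out.astype(np.uint8)


# ---------------------------------------------------------------- triangle


class TestTriangleThreshold:
    def test_two_spike_histogram_separates_populations(self):
        hist = np.zeros(256)
        hist[50] = 1000
        hist[200] = 1000
        level = triangle_threshold(hist, "dark")
        assert 50 < level < 200
        assert level == triangle_oracle(hist, "dark")

    def test_single_nonzero_bin_sentinel(self):
        hist = np.zeros(256)
        hist[77] = 12
        assert triangle_threshold(hist, "dark") == 77
        assert triangle_threshold(hist, "bright") == 77

    def test_all_zero_histogram_raises(self):
        with pytest.raises(DegenerateHistogramError):
            triangle_threshold(np.zeros(256))

    @pytest.mark.parametrize("background", ["dark", "bright"])
    def test_matches_oracle_on_bimodal_mixtures(self, background, rng):
        for _ in range(100):
            n1, n2 = rng.integers(200, 5000, size=2)
            m1, m2 = sorted(rng.integers(10, 246, size=2))
            s1, s2 = rng.uniform(3, 25, size=2)
            samples = np.concatenate(
                [rng.normal(m1, s1, n1), rng.normal(m2, s2, n2)]
            )
            hist = np.bincount(np.clip(samples, 0, 255).astype(int), minlength=256)
            assert triangle_threshold(hist, background) == triangle_oracle(hist, background)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, derandomize=True)
    def test_invariant_to_uniform_count_scaling(self, seed):
        r = np.random.default_rng(seed)
        hist = r.integers(0, 1000, size=256).astype(float)
        if hist.sum() == 0:
            hist[10] = 1
        scale = float(r.uniform(0.01, 50))
        assert triangle_threshold(hist) == triangle_threshold(hist * scale)


# ---------------------------------------------------------------- threshold


class TestApplyThreshold:
    def _img(self, arr):
        return CalibratedImage(np.asarray(arr, dtype=np.uint8), pixel_size=1.0)

    def test_strictly_greater_is_foreground_on_dark_background(self):
        img = self._img(np.full((4, 4), 10))
        assert apply_threshold(img, 5, "dark").pixels.all()
        assert not apply_threshold(img, 10, "dark").pixels.any()  # strict >

    def test_polarity_flips_for_bright_background(self):
        img = self._img([[10, 200]])
        mask = apply_threshold(img, 100, "bright")
        assert mask.pixels.tolist() == [[True, False]]

    def test_two_tone_image_with_triangle_level(self):
        px = np.where(np.arange(64 * 64).reshape(64, 64) % 3 == 0, 220, 40).astype(np.uint8)
        img = self._img(px)
        level = triangle_threshold(histogram256(px), "dark")
        mask = apply_threshold(img, level, "dark")
        assert np.array_equal(mask.pixels, px == 220)
        assert mask.threshold_used == level


# ---------------------------------------------------------------- erosion


class TestErode:
    def _mask(self, arr):
        from adiposizer import BinaryMask

        return BinaryMask(np.asarray(arr, dtype=bool), pixel_size=1.0, threshold_used=0)

    def test_isolated_pixel_removed_and_block_centre_survives(self):
        m = np.zeros((7, 7), dtype=bool)
        m[1, 1] = True
        m[3:6, 3:6] = True
        out = erode(self._mask(m)).pixels
        expected = np.zeros_like(m)
        expected[4, 4] = True
        assert np.array_equal(out, expected)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(100):
            m = rng.random((64, 64)) < rng.uniform(0.3, 0.8)
            assert np.array_equal(erode(self._mask(m)).pixels, erode_oracle(m))

    @pytest.mark.parametrize("width,n", [(1, 1), (5, 1), (5, 2), (7, 3), (6, 4)])
    def test_bar_width_shrinks_by_two_per_iteration(self, width, n):
        m = np.zeros((40, 40), dtype=bool)
        m[2:38, 10 : 10 + width] = True
        out = erode(self._mask(m), iterations=n).pixels
        remaining = out[20].sum()  # mid-row width, far from bar ends
        assert remaining == max(width - 2 * n, 0)

    def test_never_increases_foreground(self, rng):
        m = rng.random((50, 50)) < 0.6
        assert erode(self._mask(m)).pixels.sum() <= m.sum()


# ---------------------------------------------------------------- outliers


class TestRemoveOutliers:
    def test_kernel_sizes_match_documented_disk_membership(self):
        assert len(disk_offsets(2.5)) == 21
        assert len(disk_offsets(5.5)) == 97
        for radius in (2.5, 5.5):
            for dy, dx in disk_offsets(radius):
                assert math.hypot(dy, dx) <= radius

    def test_isolated_speck_removed(self):
        img = np.zeros((15, 15), dtype=np.uint8)
        img[7, 7] = 255
        out = remove_outliers(img, 2.5, 50, "bright")
        assert out[7, 7] == 0
        assert np.all(out == 0)

    def test_large_block_interior_and_edges_preserved(self):
        # the block's interior and straight edges see a majority-255
        # neighbourhood (median 255), so they are not outliers; only the
        # four extreme corners have a minority neighbourhood
        img = np.zeros((40, 40), dtype=np.uint8)
        img[10:30, 10:30] = 255
        out = remove_outliers(img, 2.5, 50, "bright")
        assert np.all(out[11:29, 11:29] == 255)  # interior
        assert np.all(out[10, 12:28] == 255)  # edge runs
        assert np.all(out[29, 12:28] == 255)
        assert np.all(out[12:28, 10] == 255)
        assert np.all(out[12:28, 29] == 255)
        assert np.all(out[:9, :] == 0)  # background untouched

    @pytest.mark.parametrize("radius", [2.5, 5.5])
    @pytest.mark.parametrize("which", ["bright", "dark"])
    def test_matches_brute_force_on_random_binary_images(self, radius, which, rng):
        for _ in range(30):
            img = np.where(rng.random((64, 64)) < 0.5, 255, 0).astype(np.uint8)
            got = remove_outliers(img, radius, 50, which)
            assert np.array_equal(got, remove_outliers_oracle(img, radius, 50, which))

    def test_matches_brute_force_on_random_grayscale(self, rng):
        for _ in range(30):
            img = rng.integers(0, 256, size=(48, 48), dtype=np.uint8)
            thr = int(rng.integers(0, 120))
            got = remove_outliers(img, 2.5, thr, "bright")
            assert np.array_equal(got, remove_outliers_oracle(img, 2.5, thr, "bright"))

    def test_bright_never_raises_and_dark_never_lowers_values(self, rng):
        img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        assert np.all(remove_outliers(img, 2.5, 10, "bright") <= img)
        assert np.all(remove_outliers(img, 2.5, 10, "dark") >= img)


# ---------------------------------------------------------------- segment


class TestSegment:
    def test_deterministic_and_overlaps_true_lumens(self, small_tissue):
        image, truth = small_tissue
        mask1 = segment(image)
        mask2 = segment(image)
        assert np.array_equal(mask1.pixels, mask2.pixels)
        # per-cell Jaccard between the mask (near the cell) and the true
        # lumen disk, and overall coverage of the lumen interiors
        h, w = image.shape
        jaccards, interior_in, interior_total = [], 0, 0
        for cell in truth.cells.itertuples():
            r_px = cell.diameter_um / 2 / image.pixel_size
            pad = int(r_px + 8)
            y0, y1 = max(0, int(cell.y_px) - pad), min(h, int(cell.y_px) + pad)
            x0, x1 = max(0, int(cell.x_px) - pad), min(w, int(cell.x_px) + pad)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - cell.y_px) ** 2 + (xx - cell.x_px) ** 2
            disk = d2 <= r_px**2
            interior = d2 <= (r_px - 3) ** 2
            local = mask1.pixels[y0:y1, x0:x1]
            jaccards.append((disk & local).sum() / (disk | local).sum())
            interior_in += (interior & local).sum()
            interior_total += interior.sum()
        assert np.median(jaccards) >= 0.7
        assert interior_in / interior_total >= 0.90

    def test_blank_image_yields_empty_mask_not_crash(self):
        img = CalibratedImage(np.full((64, 64), 128, dtype=np.uint8), pixel_size=1.0)
        mask = segment(img)
        assert not mask.pixels.any()

    def test_manual_override_bypasses_triangle(self, small_tissue):
        image, _ = small_tissue
        auto = segment(image)
        forced = segment(image, SegmentationParams(manual_threshold_override=auto.threshold_used))
        assert forced.threshold_used == auto.threshold_used
        assert np.array_equal(forced.pixels, auto.pixels)
        lvl = 42
        assert segment(image, SegmentationParams(manual_threshold_override=lvl)).threshold_used == lvl
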