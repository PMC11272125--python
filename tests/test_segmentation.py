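"""Segmentation stage: colour transform, nucleus grayscale, Otsu threshold
(against an exhaustive-scan oracle), opening, watershed splitting, tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilquant import (
    DegenerateImageError,
    SegmentationParams,
    otsu_threshold,
    rgb_to_lab,
    segment_slide,
    tile_image,
    to_nucleus_grayscale,
)
from tilquant.segmentation import binarize_and_open, watershed_split


# ---------------------------------------------------------------------------
# colour transform
# ---------------------------------------------------------------------------

def _srgb_to_lab_oracle(r, g, b):
    """Hand-chained sRGB -> linear RGB -> XYZ(D65) -> LAB for one pixel."""
    def lin(u):
        u = u / 255.0
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    rl, gl, bl = lin(r), lin(g), lin(b)
    x = 0.412456 * rl + 0.357576 * gl + 0.180437 * bl
    y = 0.212673 * rl + 0.715152 * gl + 0.072175 * bl
    z = 0.019334 * rl + 0.119192 * gl + 0.950304 * bl
    xn, yn, zn = 0.95047, 1.0, 1.08883

    def f(t):
        return t ** (1 / 3) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29

    L = 116 * f(y / yn) - 16
    a = 500 * (f(x / xn) - f(y / yn))
    bb = 200 * (f(y / yn) - f(z / zn))
    return L, a, bb


class TestRgbToLab:
    def test_black_and_white_extremes(self):
        img = np.array([[[0, 0, 0], [255, 255, 255]]], dtype=np.uint8)
        lab = rgb_to_lab(img)
        assert lab[0, 0, 0] == pytest.approx(0.0, abs=1e-6)
        assert lab[0, 1, 0] == pytest.approx(100.0, abs=1e-3)
        assert lab[0, 1, 1] == pytest.approx(0.0, abs=0.02)
        assert lab[0, 1, 2] == pytest.approx(0.0, abs=0.02)

    def test_mid_gray_matches_hand_chained_transform(self):
        img = np.full((1, 1, 3), 128, dtype=np.uint8)
        lab = rgb_to_lab(img)
        L, a, b = _srgb_to_lab_oracle(128, 128, 128)
        assert lab[0, 0, 0] == pytest.approx(L, abs=0.05)
        assert lab[0, 0, 1] == pytest.approx(a, abs=0.05)
        assert lab[0, 0, 2] == pytest.approx(b, abs=0.05)


class TestNucleusGrayscale:
    def test_dark_disks_score_above_background(self):
        img = np.full((40, 40, 3), 230, dtype=np.uint8)
        img[10:20, 10:20] = 40
        gray = to_nucleus_grayscale(img)
        assert gray[15, 15] > gray[0, 0]
        assert gray.min() >= 0.0 and gray.max() <= 1.0

    def test_inverting_lightness_inverts_ranking(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(20, 20, 3), dtype=np.uint8)
        g1 = to_nucleus_grayscale(img)
        g2 = to_nucleus_grayscale(255 - img)
        # ranking of pixel scores reverses when lightness flips
        order1 = np.argsort(g1.ravel())
        corr = np.corrcoef(g1.ravel(), g2.ravel())[0, 1]
        assert corr < -0.9
        assert order1 is not None

    def test_constant_image_raises(self):
        img = np.full((10, 10, 3), 128, dtype=np.uint8)
        with pytest.raises(DegenerateImageError):
            to_nucleus_grayscale(img)

    def test_two_tone_matches_documented_formula(self):
        """Standardise L, negate, min-max rescale: a two-tone image must map
        dark -> 1 and light -> 0 exactly."""
        img = np.full((10, 10, 3), 220, dtype=np.uint8)
        img[:5] = 30
        gray = to_nucleus_grayscale(img)
        assert np.allclose(gray[:5], 1.0)
        assert np.allclose(gray[5:], 0.0)


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

def _otsu_oracle(gray, n_bins=256):
    """Exhaustive scan: directly evaluate between-class variance at every
    candidate boundary."""
    gray = np.asarray(gray, dtype=float).ravel()
    lo, hi = gray.min(), gray.max()
    hist, edges = np.histogram(gray, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    best, best_k = -1.0, None
    for k in range(n_bins - 1):
        w0 = p[: k + 1].sum()
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (p[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (p[k + 1 :] * centers[k + 1 :]).sum() / w1
        sb = w0 * w1 * (mu0 - mu1) ** 2
        if sb > best + 1e-15:
            best, best_k = sb, k
    return edges[best_k + 1]


class TestOtsu:
    def test_two_valued_image_threshold_between_modes(self):
        gray = np.array([0.1] * 40 + [0.9] * 60)
        t = otsu_threshold(gray)
        assert 0.1 < t < 0.9

    def test_matches_exhaustive_scan_on_random_histograms(self, rng):
        """Oracle equivalence on 100 random pixel populations."""
        for _ in range(100):
            n = rng.integers(50, 500)
            mode = rng.uniform()
            if mode < 0.5:  # bimodal
                g = np.concatenate(
                    [rng.normal(0.3, 0.05, n), rng.normal(0.7, 0.08, n)]
                )
            else:  # arbitrary
                g = rng.uniform(0, 1, n)
            t_impl = otsu_threshold(g)
            t_oracle = _otsu_oracle(g)
            assert t_impl == pytest.approx(t_oracle, abs=1e-12)

    def test_agrees_with_skimage_on_bimodal_data(self, rng):
        from skimage.filters import threshold_otsu

        g = np.concatenate([rng.normal(0.25, 0.05, 500), rng.normal(0.75, 0.05, 500)])
        t = otsu_threshold(g)
        assert t == pytest.approx(threshold_otsu(g, nbins=256), abs=0.01)

    def test_symmetric_histogram_tie_breaks_low(self):
        g = np.array([0.0] * 50 + [1.0] * 50)
        t = otsu_threshold(g)
        t_oracle = _otsu_oracle(g)
        assert t == pytest.approx(t_oracle, abs=1e-12)

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full(100, 0.5))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=5, max_size=200))
    def test_oracle_equivalence_property(self, vals):
        g = np.asarray(vals)
        if g.min() == g.max():
            return
        assert otsu_threshold(g) == pytest.approx(_otsu_oracle(g), abs=1e-12)


# ---------------------------------------------------------------------------
# opening and watershed
# ---------------------------------------------------------------------------

class TestBinarizeOpenWatershed:
    params = SegmentationParams()

    def test_single_pixel_speckle_removed(self):
        gray = np.zeros((20, 20))
        gray[10, 10] = 1.0
        mask = binarize_and_open(gray, 0.5, self.params)
        assert not mask.any()

    def test_solid_disk_survives_opening_with_small_loss(self):
        yy, xx = np.mgrid[-15:16, -15:16]
        gray = (yy**2 + xx**2 <= 100).astype(float)
        before = int(gray.sum())
        mask = binarize_and_open(gray, 0.5, SegmentationParams(opening_radius_px=2))
        assert mask.sum() > 0.85 * before

    def test_empty_mask_stays_empty(self):
        gray = np.zeros((10, 10))
        mask = binarize_and_open(gray, 0.5, self.params)
        assert not mask.any()
        labels = watershed_split(mask, gray, self.params)
        assert labels.max() == 0

    def test_single_convex_blob_one_label(self):
        yy, xx = np.mgrid[-20:21, -20:21]
        mask = yy**2 + xx**2 <= 144
        labels = watershed_split(mask, np.ones_like(mask, dtype=float), self.params)
        assert labels.max() == 1

    def test_two_overlapping_disks_split_near_midline(self):
        """Two radius-8 disks, centres 12 px apart: watershed must cut the
        dumbbell within 2 px of the midline."""
        yy, xx = np.mgrid[0:40, 0:60]
        d1 = (yy - 20) ** 2 + (xx - 24) ** 2 <= 64
        d2 = (yy - 20) ** 2 + (xx - 36) ** 2 <= 64
        mask = d1 | d2
        labels = watershed_split(mask, mask.astype(float), self.params)
        assert labels.max() == 2
        lab_left = labels[20, 24]
        lab_right = labels[20, 36]
        assert lab_left != lab_right
        cut_cols = [c for c in range(60) if labels[20, c] not in (0, lab_left)]
        assert min(cut_cols) >= 28  # midline at col 30


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

class TestTiling:
    def test_1000x1000_gives_100_equal_tiles(self):
        img = np.zeros((1000, 1000, 3), dtype=np.uint8)
        tiles = tile_image(img, (10, 10))
        assert len(tiles) == 100
        assert all(t.shape == (100, 100, 3) for t, _ in tiles)

    def test_reassembly_is_bit_exact(self, rng):
        img = rng.integers(0, 256, size=(1005, 998, 3), dtype=np.uint8)
        tiles = tile_image(img, (10, 10))
        rebuilt = np.zeros_like(img)
        for t, (r0, c0) in tiles:
            rebuilt[r0 : r0 + t.shape[0], c0 : c0 + t.shape[1]] = t
        assert np.array_equal(rebuilt, img)

    def test_remainder_goes_to_last_row_and_column(self):
        img = np.zeros((1005, 998), dtype=np.uint8)
        tiles = tile_image(img, (10, 10))
        shapes = [t.shape for t, _ in tiles]
        # floor gives 100x99 tiles; remainders (5 rows, 8 cols) go to the last
        # row/column tiles
        assert shapes[0] == (100, 99)
        assert shapes[9] == (100, 107)          # last column of first row
        assert shapes[-1] == (105, 107)         # bottom-right tile
        assert sum(s[0] * s[1] for s in shapes) == 1005 * 998

    def test_image_smaller_than_grid_single_tile(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        tiles = tile_image(img, (10, 10))
        assert len(tiles) == 1 and tiles[0][1] == (0, 0)


# ---------------------------------------------------------------------------
# whole-slide composition
# ---------------------------------------------------------------------------

class TestSegmentSlide:
    def test_blank_slide_yields_no_nuclei(self):
        img = np.full((200, 200, 3), 230, dtype=np.uint8)
        labels = segment_slide(img)
        assert labels.max() == 0

    def test_segmentation_is_deterministic(self, benchmark_slide):
        img, _ = benchmark_slide
        l1 = segment_slide(img)
        l2 = segment_slide(img)
        assert np.array_equal(l1, l2)

    def test_labelled_area_within_foreground(self, benchmark_slide):
        img, _ = benchmark_slide
        params = SegmentationParams()
        gray = to_nucleus_grayscale(img)
        t = otsu_threshold(gray)
        mask = binarize_and_open(gray, t, params)
        labels = segment_slide(img, params)
        assert ((labels > 0) & ~mask).sum() == 0
        ids = np.unique(labels)
        assert ids[-1] == len(ids) - 1  # contiguous labels
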