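"""HSV masking, thresholding, component selection and ROI placement."""

import colorsys
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafvi import segmentation as seg
from leafvi.errors import DegenerateHistogram, EmptySegmentation, InvalidROI


def hsv_pixel(h_deg, s, v):
    """8-bit RGB pixel from HSV (h in degrees)."""
    r, g, b = colorsys.hsv_to_rgb(h_deg / 360.0, s, v)
    return np.array([round(r * 255), round(g * 255), round(b * 255)], dtype=np.uint8)


def patch_image(shape=(20, 30), patch=(slice(5, 12), slice(8, 20)),
                fg=(120.0, 0.8, 0.6), bg=(30.0, 0.6, 0.5)):
    img = np.empty((*shape, 3), dtype=np.uint8)
    img[:, :] = hsv_pixel(*bg)
    img[patch] = hsv_pixel(*fg)
    return img, patch


class TestRgbToHsv:
    def test_primary_green(self):
        hsv = seg.rgb_to_hsv(np.array([[[0, 255, 0]]], dtype=np.uint8))
        assert hsv[0, 0] == pytest.approx([120.0, 1.0, 1.0])

    def test_achromatic_gray(self):
        hsv = seg.rgb_to_hsv(np.array([[[128, 128, 128]]], dtype=np.uint8))
        assert hsv[0, 0, 1] == 0.0
        assert hsv[0, 0, 2] == pytest.approx(128 / 255)
        assert hsv[0, 0, 0] == 0.0  # hue undefined -> reported as 0

    def test_matches_reference_conversion(self, rng):
        pixels = rng.integers(0, 256, (100, 100, 3)).astype(np.uint8)
        hsv = seg.rgb_to_hsv(pixels)
        for r, c in zip(*np.unravel_index(np.arange(10000), (100, 100))):
            rr, gg, bb = (int(v) / 255.0 for v in pixels[r, c])
            h, s, v = colorsys.rgb_to_hsv(rr, gg, bb)
            assert abs(hsv[r, c, 0] - h * 360.0) < 1e-6
            assert abs(hsv[r, c, 1] - s) < 1e-9
            assert abs(hsv[r, c, 2] - v) < 1e-9


class TestGreennessMask:
    def test_green_patch_on_brown_background(self):
        img, patch = patch_image()
        mask = seg.greenness_mask(seg.rgb_to_hsv(img))
        expected = np.zeros(img.shape[:2], dtype=bool)
        expected[patch] = True
        assert np.array_equal(mask, expected)

    def test_all_black_image_empty(self):
        img = np.zeros((5, 5, 3), dtype=np.uint8)
        assert not seg.greenness_mask(seg.rgb_to_hsv(img)).any()

    def test_shadowed_half_excluded_by_value_bound(self):
        # same green hue, one half rendered dark (v=0.1 < lower v=0.25)
        img = np.empty((10, 10, 3), dtype=np.uint8)
        img[:, :5] = hsv_pixel(120.0, 0.8, 0.6)
        img[:, 5:] = hsv_pixel(120.0, 0.8, 0.1)
        mask = seg.greenness_mask(seg.rgb_to_hsv(img))
        assert mask[:, :5].all() and not mask[:, 5:].any()

    def test_full_hsv_window_accepts_everything(self, rng):
        img = rng.integers(0, 256, (8, 8, 3)).astype(np.uint8)
        full = seg.HSVBounds(lower=(0.0, 0.0, 0.0), upper=(360.0, 1.0, 1.0))
        assert seg.greenness_mask(seg.rgb_to_hsv(img), full).all()

    def test_disjoint_window_accepts_nothing(self):
        img, _ = patch_image()
        narrow = seg.HSVBounds(lower=(350.0, 0.9, 0.9), upper=(355.0, 1.0, 1.0))
        assert not seg.greenness_mask(seg.rgb_to_hsv(img), narrow).any()


def brute_otsu(hist):
    total = sum(hist)
    best_var, best_t = -1.0, None
    for t in range(255):
        w0 = sum(hist[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(i * hist[i] for i in range(t + 1)) / w0
        mu1 = sum(i * hist[i] for i in range(t + 1, 256)) / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def brute_triangle(hist):
    hist = list(hist)
    peak = max(range(256), key=lambda b: (hist[b], -b))
    occupied = [b for b in range(256) if hist[b] > 0]
    tail = max(occupied, key=lambda b: abs(b - peak))
    lo, hi = min(peak, tail), max(peak, tail)
    span = tail - peak
    y_tail = hist[tail] / hist[peak]
    best_d, best_b = -1.0, lo
    for b in range(lo + 1, hi):
        xp = (b - peak) / span
        yp = hist[b] / hist[peak]
        d = abs((yp - 1.0) - (y_tail - 1.0) * xp) / np.hypot(1.0, y_tail - 1.0)
        if d > best_d:  # strict: first maximum wins, like the lowest-bin tie rule
            best_d, best_b = d, b
    return best_b


class TestThresholds:
    def test_otsu_separates_two_spikes(self):
        hist = np.zeros(256, dtype=int)
        hist[10], hist[200] = 40, 60
        level = seg.otsu_level(hist)
        assert 10 <= level < 200
        img = np.array([10, 200], dtype=np.uint8)
        assert np.array_equal(seg.binarize(img, level), [False, True])

    def test_otsu_matches_exhaustive_search(self, rng):
        for _ in range(200):
            hist = rng.integers(0, 50, 256)
            if np.count_nonzero(hist) < 2:
                continue
            assert seg.otsu_level(hist) == brute_otsu(hist.tolist())

    def test_otsu_degenerate_single_bin(self):
        hist = np.zeros(256, dtype=int)
        hist[50] = 100
        with pytest.raises(DegenerateHistogram):
            seg.otsu_level(hist)

    def test_triangle_right_triangle_matches_geometry(self):
        hist = np.zeros(256, dtype=int)
        for b in range(100):
            hist[b] = 100 - b
        assert seg.triangle_level(hist) == brute_triangle(hist)

    def test_triangle_two_spikes_strictly_between(self):
        hist = np.zeros(256, dtype=int)
        hist[0], hist[255] = 50, 30
        level = seg.triangle_level(hist)
        assert 0 < level < 255

    def test_triangle_matches_exhaustive_search(self, rng):
        for _ in range(100):
            hist = rng.integers(0, 50, 256)
            if np.count_nonzero(hist) < 2:
                continue
            assert seg.triangle_level(hist) == brute_triangle(hist.tolist())

    def test_triangle_degenerate(self):
        hist = np.zeros(256, dtype=int)
        hist[7] = 9
        with pytest.raises(DegenerateHistogram):
            seg.triangle_level(hist)

    def test_binarize_semantics(self, rng):
        img = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        assert np.array_equal(seg.binarize(img, 0), img == 255)
        assert not seg.binarize(img, 255).any()
        grid = rng.integers(0, 256, (13, 17))
        level = int(rng.integers(0, 256))
        assert seg.binarize(grid, level).sum() == sum(
            1 for v in grid.ravel() if v > level)


def flood_fill_components(mask, connectivity):
    """Reference BFS labeling."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    for r0, c0 in np.argwhere(mask):
        if seen[r0, c0]:
            continue
        queue = deque([(int(r0), int(c0))])
        seen[r0, c0] = True
        members = []
        while queue:
            r, c = queue.popleft()
            members.append((r, c))
            for dr, dc in steps:
                rr, cc = r + dr, c + dc
                if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] \
                        and mask[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    queue.append((rr, cc))
        comps.append(frozenset(members))
    return set(comps)


class TestConnectedComponents:
    def test_two_disjoint_squares(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0:3, 0:3] = True
        mask[6:9, 6:9] = True
        comps = seg.connected_components(mask)
        assert sorted(c.area for c in comps) == [9, 9]

    def test_diagonal_connectivity_semantics(self):
        mask = np.eye(5, dtype=bool)
        assert len(seg.connected_components(mask, connectivity=8)) == 1
        assert len(seg.connected_components(mask, connectivity=4)) == 5

    def test_areas_sum_to_true_pixels(self, rng):
        mask = rng.random((20, 20)) < 0.4
        comps = seg.connected_components(mask)
        assert sum(c.area for c in comps) == int(mask.sum())

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill(self, rng, connectivity):
        for _ in range(50):
            mask = rng.random((16, 16)) < rng.uniform(0.2, 0.6)
            comps = seg.connected_components(mask, connectivity=connectivity)
            got = {frozenset(map(tuple, c.pixels)) for c in comps}
            assert got == flood_fill_components(mask, connectivity)


class TestLargestComponent:
    def test_picks_maximal_area(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[0:3, 0:3] = True  # 9
        mask[5:15, 5:15] = True  # 100
        mask[20:22, 20:22] = True  # 4
        comp = seg.largest_component(seg.connected_components(mask), mask.shape)
        assert comp.area == 100

    def test_area_tie_prefers_centered(self):
        mask = np.zeros((21, 21), dtype=bool)
        mask[9:12, 9:12] = True  # centered 3x3
        mask[0:3, 0:3] = True  # corner 3x3
        comp = seg.largest_component(seg.connected_components(mask), mask.shape)
        assert comp.centroid == (10.0, 10.0)

    def test_empty_raises(self):
        with pytest.raises(EmptySegmentation):
            seg.largest_component([], (10, 10))


class TestComponentMidpoint:
    def test_symmetric_square(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:15, 10:15] = True
        comp = seg.connected_components(mask)[0]
        assert seg.component_midpoint(comp) == (12, 12)

    def test_concave_shape_returns_member(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[0, 0:5] = True
        mask[4, 0:5] = True
        mask[1:4, 0] = True  # "C" open to the right; centroid in the cavity
        comp = seg.connected_components(mask)[0]
        mid = seg.component_midpoint(comp)
        assert mask[mid]
        # nearest member to the centroid, ties to smaller row/col
        cr, cc = comp.centroid
        d2 = [(r - cr) ** 2 + (c - cc) ** 2 for r, c in map(tuple, comp.pixels)]
        assert (mid in map(tuple, comp.pixels)) and \
            d2[list(map(tuple, comp.pixels)).index(mid)] == min(d2)

    def test_single_pixel(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[3, 1] = True
        comp = seg.connected_components(mask)[0]
        assert seg.component_midpoint(comp) == (3, 1)


class TestPlaceRoi:
    def test_centered_rectangle(self):
        roi, info = seg.place_roi((256, 256), (512, 512), size=(10, 10))
        assert (roi.x1, roi.y1, roi.x2, roi.y2) == (251, 251, 261, 261)
        assert info["contained"]

    def test_clamped_near_border(self):
        roi, _ = seg.place_roi((2, 2), (512, 512), size=(10, 10))
        assert roi.x1 == 0 and roi.y1 == 0
        assert roi.x2 <= 512 and roi.y2 <= 512

    def test_shrinks_to_fit_small_blob(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:16, 10:16] = True  # 6x6 blob
        comp = seg.connected_components(mask)[0]
        mid = seg.component_midpoint(comp)
        roi, info = seg.place_roi(mid, mask.shape, size=(10, 10), mask=mask)
        assert info["contained"]
        # exhaustive containment check
        for r in range(roi.y1, roi.y2):
            for c in range(roi.x1, roi.x2):
                assert mask[r, c]

    def test_degrades_with_warning_not_error(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, 5] = True  # single pixel: even min size cannot fit
        roi, info = seg.place_roi((5, 5), mask.shape, size=(10, 10), mask=mask)
        assert not info["contained"]
        assert 0.0 < info["coverage"] < 1.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 99), st.integers(0, 79), st.integers(1, 30), st.integers(1, 30))
    def test_roi_invariants_always_hold(self, r, c, h, w):
        roi, _ = seg.place_roi((r, c), (100, 80), size=(h, w))
        assert 0 <= roi.x1 < roi.x2 <= 80
        assert 0 <= roi.y1 < roi.y2 <= 100


class TestManualRoi:
    def test_reference_coordinates(self):
        roi = seg.manual_roi(203, 213, 268, 278, (512, 512))
        assert roi.width == 65 and roi.height == 65

    def test_zero_width_rejected(self):
        with pytest.raises(InvalidROI):
            seg.manual_roi(10, 10, 10, 20, (512, 512))

    def test_whole_frame(self):
        roi = seg.manual_roi(0, 0, 512, 512, (512, 512))
        assert roi.width == roi.height == 512

    def test_out_of_bounds_rejected(self):
        with pytest.raises(InvalidROI):
            seg.manual_roi(0, 0, 513, 512, (512, 512))


class TestAutoRoi:
    def test_phantom_midpoint_in_lit_leaf(self, noiseless_scene):
        roi, diag = seg.auto_roi(noiseless_scene.rgb)
        assert noiseless_scene.masks["lit"][diag.midpoint]
        assert diag.roi_contained

    def test_fully_dark_scene_raises_empty_segmentation(self):
        img = np.full((32, 32, 3), 10, dtype=np.uint8)  # everything below v bound
        with pytest.raises(EmptySegmentation):
            seg.auto_roi(img)

    def test_otsu_and_triangle_agree_on_phantom(self, noiseless_scene):
        roi_o, _ = seg.auto_roi(noiseless_scene.rgb, method="otsu")
        roi_t, _ = seg.auto_roi(noiseless_scene.rgb, method="triangle")
        assert roi_o == roi_t
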