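"""HSV conversion, thresholding, contour tracing, marker filtering."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from fingergonio.errors import SegmentationError
from fingergonio.segmentation import (
    BinaryMask,
    MarkerContour,
    ThresholdSpec,
    auto_threshold,
    filter_marker_contours,
    find_contours,
    hsv_in_range,
    order_along_chain,
    rgb_to_hsv,
    threshold_segment,
    to_gray,
)


def _px(rgb):
    return np.asarray(rgb, dtype=np.uint8).reshape(1, 1, 3)


class TestRgbToHsv:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 0, 0), (0.0, 255.0, 255.0)),       # red
        ((0, 255, 0), (60.0, 255.0, 255.0)),      # green: 120 deg / 2
        ((0, 0, 255), (120.0, 255.0, 255.0)),     # blue: 240 deg / 2
        ((255, 255, 0), (30.0, 255.0, 255.0)),    # yellow
        ((0, 255, 255), (90.0, 255.0, 255.0)),    # cyan
        ((255, 0, 255), (150.0, 255.0, 255.0)),   # magenta
        ((100, 100, 100), (0.0, 0.0, 100.0)),     # achromatic gray
        ((0, 0, 0), (0.0, 0.0, 0.0)),             # black, V = 0 branch
    ])
    def test_primaries_secondaries_achromatics(self, rgb, expected):
        assert np.allclose(rgb_to_hsv(_px(rgb))[0, 0], expected)

    def test_negative_hue_wraps(self):
        # V = R with B > G gives a negative raw hue, wrapped by +360
        h, s, v = rgb_to_hsv(_px((200, 0, 100)))[0, 0]
        assert 0.0 <= h < 180.0
        assert h == pytest.approx((360 - 60 * 100 / 200) / 2)

    @settings(max_examples=50, deadline=None)
    @given(st.tuples(st.integers(0, 255), st.integers(0, 255),
                     st.integers(0, 255)))
    def test_matches_skimage_reference(self, rgb):
        """Cross-check the conversion against skimage on random colors."""
        from skimage.color import rgb2hsv

        ours = rgb_to_hsv(_px(rgb))[0, 0]
        ref = rgb2hsv(np.asarray(rgb, dtype=float).reshape(1, 1, 3) / 255.0)
        ref_h = ref[0, 0, 0] * 360.0 / 2.0
        ref_s = ref[0, 0, 1] * 255.0
        ref_v = ref[0, 0, 2] * 255.0
        assert min(abs(ours[0] - ref_h), 180 - abs(ours[0] - ref_h)) < 1e-6
        assert ours[1] == pytest.approx(ref_s, abs=1e-6)
        assert ours[2] == pytest.approx(ref_v, abs=1e-6)


class TestHsvInRange:
    def test_marker_blue_inside_default_gates(self):
        mask = hsv_in_range(np.array([[[120.0, 200.0, 200.0]]]))
        assert mask.is_target[0, 0]

    def test_red_outside_default_gates(self):
        mask = hsv_in_range(np.array([[[0.0, 255.0, 255.0]]]))
        assert not mask.is_target[0, 0]

    def test_all_background_image(self):
        hsv = np.zeros((5, 5, 3))
        mask = hsv_in_range(hsv)
        assert not mask.is_target.any()
        assert set(np.unique(mask.values)) == {mask.background}

    def test_inverted_bounds_rejected(self):
        with pytest.raises(SegmentationError, match="inverted"):
            hsv_in_range(np.zeros((2, 2, 3)), lo=(130, 0, 0), hi=(100, 255,
                                                                  255))


class TestToGray:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 255, 255), 255), ((0, 0, 0), 0), ((255, 0, 0), 76),
    ])
    def test_luma_values(self, rgb, expected):
        assert to_gray(_px(rgb))[0, 0] == expected


class TestAutoThreshold:
    def test_two_level_image_separated(self):
        img = np.array([[50] * 10, [200] * 10], dtype=np.uint8)
        spec = auto_threshold(img)
        assert 50 <= spec.t < 200
        m = threshold_segment(img, spec)
        assert m.is_target[0].all() and not m.is_target[1].any()

    def test_constant_image_errors(self):
        with pytest.raises(SegmentationError, match="single gray level"):
            auto_threshold(np.full((4, 4), 7, dtype=np.uint8))

    def test_equals_exhaustive_between_class_variance_search(self, rng):
        """Otsu choice equals brute-force maximization over all 256
        thresholds on a bimodal Gaussian-mixture image."""
        img = np.clip(np.concatenate([
            rng.normal(80, 12, 4000), rng.normal(190, 18, 2500)
        ]).round(), 0, 255).astype(np.uint8).reshape(65, 100)
        spec = auto_threshold(img)

        levels = img.ravel().astype(float)
        best_t, best_v = None, -1.0
        for t in range(256):
            lo = levels[levels <= t]
            hi = levels[levels > t]
            if len(lo) == 0 or len(hi) == 0:
                v = 0.0
            else:
                w0 = len(lo) / len(levels)
                v = w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2
            if v > best_v + 1e-12:
                best_t, best_v = t, v
        assert spec.t == best_t

    def test_close_to_skimage_otsu(self, rng):
        from skimage.filters import threshold_otsu

        img = np.clip(np.concatenate([
            rng.normal(70, 10, 3000), rng.normal(180, 15, 3000)
        ]).round(), 0, 255).astype(np.uint8).reshape(60, 100)
        assert abs(auto_threshold(img).t - threshold_otsu(img)) <= 1


class TestThresholdSegment:
    def test_pointwise_rule_2x2(self):
        img = np.array([[10, 200], [90, 150]], dtype=np.uint8)
        m = threshold_segment(img, ThresholdSpec(t=100))
        assert np.array_equal(m.values, [[0, 255], [0, 255]])

    def test_all_above_threshold_uniform_background(self):
        m = threshold_segment(np.full((3, 3), 220, dtype=np.uint8),
                              ThresholdSpec(t=100))
        assert (m.values == 255).all()

    def test_idempotent_on_own_output(self):
        img = (np.arange(64, dtype=np.uint8).reshape(8, 8) * 4)
        spec = ThresholdSpec(t=128)
        once = threshold_segment(img, spec)
        twice = threshold_segment(once.values.astype(np.uint8), spec)
        assert np.array_equal(once.values, twice.values)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 255))
    def test_output_two_valued(self, t):
        rng = np.random.default_rng(t)
        img = rng.integers(0, 256, size=(12, 9)).astype(np.uint8)
        m = threshold_segment(img, ThresholdSpec(t=t))
        assert set(np.unique(m.values)) <= {0, 255}


def _blob_mask(rng, shape=(48, 48)):
    field = ndimage.gaussian_filter(rng.normal(size=shape), 4.0)
    # fill holes: the traced outer boundary should enclose solid regions
    return BinaryMask.from_bool(
        ndimage.binary_fill_holes(field > np.quantile(field, 0.8)))


class TestFindContours:
    def test_filled_square(self):
        m = np.full((20, 20), 255, dtype=np.uint8)
        m[5:15, 5:15] = 0
        cs = find_contours(BinaryMask(m))
        assert len(cs) == 1
        c = cs[0]
        assert c.pixel_count == 100
        # pixel-center shoelace of a 10x10 block is 9x9
        assert c.area == pytest.approx(81.0)
        assert abs(c.pixel_count - c.area) <= len(c.points)
        # closed: first adjacent to last
        assert np.abs(c.points[0] - c.points[-1]).max() <= 1

    def test_two_disjoint_squares(self):
        m = np.full((20, 30), 255, dtype=np.uint8)
        m[2:8, 2:8] = 0
        m[10:16, 20:26] = 0
        assert len(find_contours(BinaryMask(m))) == 2

    def test_empty_mask(self):
        assert find_contours(
            BinaryMask(np.full((5, 5), 255, dtype=np.uint8))) == []

    def test_l_shape_area_matches_pixel_count_within_bound(self):
        m = np.full((20, 20), 255, dtype=np.uint8)
        m[3:15, 3:7] = 0
        m[11:15, 3:17] = 0
        (c,) = find_contours(BinaryMask(m))
        expected = (m == 0).sum()
        assert c.pixel_count == expected
        assert abs(c.area - expected) <= len(c.points)

    def test_random_blobs_shoelace_vs_pixel_count(self):
        """Shoelace area tracks brute-force pixel counting on 50 random
        blob regions within the boundary-convention bound."""
        rng = np.random.default_rng(4242)
        checked = 0
        while checked < 50:
            for c in find_contours(_blob_mask(rng), min_pixels=8):
                assert abs(c.area - c.pixel_count) <= len(c.points) + 1
                checked += 1
        assert checked >= 50


class TestFilterMarkerContours:
    @staticmethod
    def _fake(area, cx):
        pts = np.array([[cx, 0], [cx + 1, 0], [cx + 1, 1], [cx, 1]],
                       dtype=float)
        return MarkerContour(points=pts, area=area, pixel_count=int(area),
                             centroid=np.array([cx, 0.5]))

    def test_picks_similar_area_subset(self):
        areas = [100, 102, 98, 101, 10, 500]
        cs = [self._fake(a, 10 * i) for i, a in enumerate(areas)]
        got = sorted(c.area for c in filter_marker_contours(cs, tol=0.2))
        assert got == [98, 100, 101, 102]

    def test_equals_exhaustive_search(self, rng):
        """Selection equals brute-force minimization of the relative area
        spread over all 4-subsets, for up to 12 contours."""
        for _ in range(20):
            n = rng.integers(4, 13)
            areas = rng.uniform(10, 500, size=n)
            cs = [self._fake(a, 10 * i) for i, a in enumerate(areas)]
            best = min(
                combinations(range(n), 4),
                key=lambda s: (areas[list(s)].max() - areas[list(s)].min())
                / areas[list(s)].mean(),
            )
            try:
                got = filter_marker_contours(cs, tol=np.inf)
            except SegmentationError:
                continue
            assert sorted(c.area for c in got) == sorted(
                areas[list(best)].tolist())

    def test_exactly_four_equal_areas(self):
        cs = [self._fake(50, 10 * i) for i in range(4)]
        assert len(filter_marker_contours(cs)) == 4

    def test_dissimilar_areas_fail(self):
        cs = [self._fake(a, 10 * i) for i, a in enumerate([100, 100, 100,
                                                           1])]
        with pytest.raises(SegmentationError, match="spread"):
            filter_marker_contours(cs, tol=0.2)

    def test_fewer_than_four_fail(self):
        cs = [self._fake(50, 10 * i) for i in range(3)]
        with pytest.raises(SegmentationError, match="found 3"):
            filter_marker_contours(cs)


class TestOrderAlongChain:
    def test_straight_chain_left_to_right(self):
        pts = np.array([[30, 5], [10, 5], [40, 5], [20, 5]])
        assert list(order_along_chain(pts)) == [1, 3, 0, 2]

    def test_curled_chain_follows_path_not_projection(self):
        # spiral layout where principal-axis projection mis-orders
        pts = np.array([[15.0, 0.0], [30.0, 17.5], [19.0, 35.0],
                        [8.0, 27.0]])
        order = list(order_along_chain(pts))
        assert order in ([0, 1, 2, 3], [3, 2, 1, 0])

    def test_proximal_hint_orients(self):
        pts = np.array([[10.0, 5.0], [20, 5], [30, 5], [40, 5]])
        assert list(order_along_chain(pts, proximal_hint=(45, 5))) == \
            [3, 2, 1, 0]
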