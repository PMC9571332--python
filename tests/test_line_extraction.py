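"""Canny stages, Hough accumulator, least-squares fits, marker axes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fingergonio import SceneSpec, render_scene
from fingergonio.config import PipelineConfig
from fingergonio.errors import LineExtractionError
from fingergonio.line_extraction import (
    HoughLine,
    Line2D,
    canny,
    extract_marker_axes,
    hough_lines,
    lsq_fit_line,
    quantize_gradient_direction,
)
from fingergonio.segmentation import (
    filter_marker_contours,
    find_contours,
    threshold_segment,
    to_gray,
    ThresholdSpec,
)


# --------------------------------------------------------------------------
# independent brute-force Hough oracle (plain loops, same binning contract)


def brute_force_hough(edges, rho_res=1.0, theta_res=1.0, vote_threshold=10):
    ys, xs = np.nonzero(np.asarray(edges, dtype=bool))
    thetas = [t * theta_res for t in range(int(np.ceil(180.0 / theta_res)))]
    diag = float(np.hypot(*edges.shape))
    n_half = int(np.ceil(diag / rho_res))
    acc = {}
    for x, y in zip(xs.tolist(), ys.tolist()):
        for j, th in enumerate(thetas):
            r = x * np.cos(np.deg2rad(th)) + y * np.sin(np.deg2rad(th))
            i = int(round(r / rho_res)) + n_half
            acc[(i, j)] = acc.get((i, j), 0) + 1
    peaks = []
    for (i, j), v in acc.items():
        if v < vote_threshold:
            continue
        neighbours = [acc.get((i + di, j + dj), 0)
                      for di in (-1, 0, 1) for dj in (-1, 0, 1)
                      if not (di == 0 and dj == 0)
                      and 0 <= i + di < 2 * n_half + 1
                      and 0 <= j + dj < len(thetas)]
        if all(v >= nv for nv in neighbours):
            peaks.append(HoughLine(rho=float((i - n_half) * rho_res),
                                   theta_deg=float(thetas[j]), votes=v))
    peaks.sort(key=lambda l: (-l.votes, l.theta_deg, l.rho))
    return peaks


def _mask_collection():
    masks = []
    m = np.zeros((30, 30), dtype=bool)
    m[5:25, 5] = True
    masks.append(("vertical", m))
    m = np.zeros((30, 30), dtype=bool)
    m[3, 2:28] = True
    masks.append(("horizontal", m))
    m = np.zeros((40, 40), dtype=bool)
    np.fill_diagonal(m, True)
    masks.append(("diagonal", m))
    rng = np.random.default_rng(77)
    for k in range(5):
        m = np.zeros((48, 64), dtype=bool)
        # a random line segment plus scattered noise points
        x0, y0 = rng.integers(0, 20, 2)
        dx, dy = rng.integers(1, 5, 2)
        for t in range(25):
            x, y = x0 + t * dx // 3, y0 + t * dy // 3
            if x < 64 and y < 48:
                m[y, x] = True
        pts = rng.integers(0, [48, 64], size=(30, 2))
        m[pts[:, 0], pts[:, 1]] = True
        masks.append((f"random-{k}", m))
    return masks


class TestHoughLines:
    def test_vertical_line_peak(self):
        m = np.zeros((25, 25), dtype=bool)
        m[2:22, 5] = True
        top = hough_lines(m, vote_threshold=10)[0]
        assert top.theta_deg == 0.0 and top.rho == 5.0 and top.votes == 20

    def test_horizontal_line_peak(self):
        m = np.zeros((25, 25), dtype=bool)
        m[3, 2:22] = True
        lines = hough_lines(m, vote_threshold=10)
        # adjacent theta bins can tie at full votes for short segments;
        # the true line must be among the maximal-vote peaks
        maximal = [l for l in lines if l.votes == lines[0].votes]
        assert HoughLine(rho=3.0, theta_deg=90.0,
                         votes=20) in maximal

    def test_diagonal_through_origin(self):
        m = np.zeros((30, 30), dtype=bool)
        np.fill_diagonal(m, True)
        top = hough_lines(m, vote_threshold=10)[0]
        assert top.theta_deg == 135.0 and top.rho == 0.0

    def test_empty_mask(self):
        assert hough_lines(np.zeros((10, 10), dtype=bool)) == []

    def test_invalid_resolution(self):
        with pytest.raises(LineExtractionError):
            hough_lines(np.ones((4, 4), dtype=bool), rho_res=0)

    @pytest.mark.parametrize("name,mask", _mask_collection())
    def test_equals_brute_force_accumulator(self, name, mask):
        """Peak list identical to an independently coded accumulator on
        small masks."""
        got = hough_lines(mask, vote_threshold=8)
        ref = brute_force_hough(mask, vote_threshold=8)
        assert got == ref


class TestLsqFitLine:
    def test_exact_line(self):
        fit = lsq_fit_line([(0, 1), (1, 3), (2, 5)], axis="y-on-x")
        assert fit.a == pytest.approx(2.0)
        assert fit.b == pytest.approx(1.0)
        assert fit.residual == pytest.approx(0.0, abs=1e-12)
        # auto mode fits the steeper direction but is the same line
        auto = lsq_fit_line([(0, 1), (1, 3), (2, 5)])
        assert auto.axis == "x-on-y"
        assert np.allclose(auto.to_line().distance([(0, 1), (2, 5)]), 0,
                           atol=1e-9)

    def test_closed_form_sums(self):
        # N=3, sum x=3, sum y=1, sum xy=1, sum x^2=5 -> a=0, b=1/3
        fit = lsq_fit_line([(0, 0), (1, 1), (2, 0)])
        assert fit.a == pytest.approx(0.0)
        assert fit.b == pytest.approx(1 / 3)

    def test_vertical_points_axis_swapped(self):
        fit = lsq_fit_line([(4, 0), (4, 1), (4, 7)])
        assert fit.axis == "x-on-y"
        d = fit.to_line().direction
        assert abs(d[0]) < 1e-12 and abs(d[1]) == pytest.approx(1.0)

    def test_identical_points_rejected(self):
        with pytest.raises(LineExtractionError, match="identical"):
            lsq_fit_line([(1, 1), (1, 1), (1, 1)])

    def test_matches_polyfit_oracle(self, rng):
        """Closed-form (a, b) equals numpy's polynomial LSQ on random
        well-conditioned point sets."""
        for _ in range(20):
            x = rng.uniform(0, 10, size=15)
            y = 2.5 * x - 1.0 + rng.normal(0, 1.0, size=15)
            fit = lsq_fit_line(np.column_stack([x, y]), axis="y-on-x")
            a_ref, b_ref = np.polyfit(x, y, 1)
            assert fit.a == pytest.approx(a_ref, abs=1e-9)
            assert fit.b == pytest.approx(b_ref, abs=1e-9)

    @settings(max_examples=30, deadline=None)
    @given(a=st.floats(-3, 3), b=st.floats(-20, 20),
           seed=st.integers(0, 10_000))
    def test_recovers_generating_line(self, a, b, seed):
        """Exact recovery on collinear points; 3-sigma bounds on noisy."""
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 20, 30)
        exact = lsq_fit_line(np.column_stack([x, a * x + b]),
                             axis="y-on-x")
        assert exact.a == pytest.approx(a, abs=1e-9)
        assert exact.b == pytest.approx(b, abs=1e-9)

        sigma = 0.5
        y = a * x + b + rng.normal(0, sigma, size=x.size)
        fit = lsq_fit_line(np.column_stack([x, y]), axis="y-on-x")
        sxx = ((x - x.mean()) ** 2).sum()
        se_a = sigma / np.sqrt(sxx)
        se_b = sigma * np.sqrt(1 / len(x) + x.mean() ** 2 / sxx)
        assert abs(fit.a - a) < 5 * se_a + 1e-9
        assert abs(fit.b - b) < 5 * se_b + 1e-9


class TestCanny:
    def test_constant_image_no_edges(self):
        assert not canny(np.full((20, 20), 77.0)).any()

    def test_vertical_step_single_column(self):
        img = np.zeros((20, 30))
        img[:, 15:] = 200.0
        edges = canny(img)
        interior = edges[5:15]
        assert (interior.sum(axis=1) == 1).all()
        # finite-difference oracle: the max-gradient column
        sm_cols = np.abs(np.diff(img[10])).argmax()
        edge_cols = np.nonzero(interior[0])[0]
        assert abs(edge_cols[0] - sm_cols) <= 1

    @pytest.mark.parametrize("deg,expected", [
        (30, 45), (0, 0), (91, 90), (130, 135), (170, 0), (-45, 135),
    ])
    def test_direction_quantization(self, deg, expected):
        assert quantize_gradient_direction(np.array([deg]))[0] == expected

    def test_invalid_thresholds(self):
        with pytest.raises(LineExtractionError, match="thresholds"):
            canny(np.zeros((5, 5)), low=100, high=50)

    def test_rendered_markers_all_have_edges(self, clean_scene):
        """Every rendered marker boundary yields edge pixels at default
        parameters."""
        img, truth = clean_scene
        mask = threshold_segment(to_gray(img), ThresholdSpec(t=120))
        edges = canny(mask.values.astype(float))
        for corners in truth.corners_px:
            x0, y0 = corners.min(axis=0).astype(int) - 2
            x1, y1 = corners.max(axis=0).astype(int) + 3
            assert edges[y0:y1, x0:x1].sum() > 0


def _scene_axes(spec, method="hough"):
    img, truth = render_scene(spec)
    mask = threshold_segment(to_gray(img), ThresholdSpec(t=120))
    contours = filter_marker_contours(
        find_contours(mask, min_pixels=20),
        proximal_hint=truth.hinge_px[0])
    edges = canny(mask.values.astype(float)) if method == "hough" else None
    return extract_marker_axes(contours, method=method, edges=edges), truth


class TestExtractMarkerAxes:
    def test_straight_chain_directions_parallel(self):
        spec = SceneSpec(angles=(180, 180, 180), noise_sigma=0,
                         texture_amplitude=0, seed=2)
        axes, _ = _scene_axes(spec)
        dirs = np.array([a.direction for a in axes])
        for d in dirs[1:]:
            assert np.degrees(np.arccos(np.clip(abs(d @ dirs[0]), -1, 1))) \
                < 1.0

    def test_axis_angle_matches_truth_rectangle(self):
        spec = SceneSpec(angles=(145, 110, 115), noise_sigma=0,
                         texture_amplitude=0, seed=2)
        axes, truth = _scene_axes(spec)
        true_dirs = truth.marker_directions_px()
        for ax, td in zip(axes, true_dirs):
            ang = np.degrees(np.arccos(np.clip(abs(ax.direction @ td),
                                               -1, 1)))
            assert ang < 1.0

    def test_inner_labels_on_concave_side(self):
        """With a 145-degree bend the inner line of each marker sits on the
        concave side of the chain (positive bend rotation side)."""
        spec = SceneSpec(angles=(145, 110, 115), noise_sigma=0,
                         texture_amplitude=0, seed=2)
        axes, truth = _scene_axes(spec)
        for ax in axes:
            centroid = 0.5 * (ax.head + ax.tail)
            v_in = ax.inner.foot(centroid) - centroid
            v_out = ax.outer.foot(centroid) - centroid
            t = ax.direction
            # renderer bends with positive rotation: concave side has
            # positive cross product with the local chain direction
            assert t[0] * v_in[1] - t[1] * v_in[0] > 0
            assert t[0] * v_out[1] - t[1] * v_out[0] < 0

    def test_inner_outer_gap_within_bound(self):
        spec = SceneSpec(angles=(150, 120, 140), seed=6)
        axes, _ = _scene_axes(spec)
        cfg = PipelineConfig()
        for ax in axes:
            assert ax.angular_gap_deg <= cfg.measure.near_parallel_bound_deg

    def test_lsq_mode_duplicates_centerline(self):
        spec = SceneSpec(angles=(145, 110, 115), noise_sigma=0,
                         texture_amplitude=0, seed=2)
        axes, _ = _scene_axes(spec, method="lsq")
        for ax in axes:
            assert ax.inner is ax.outer

    def test_hough_mode_requires_edges(self):
        spec = SceneSpec(angles=(180, 180, 180), noise_sigma=0,
                         texture_amplitude=0, seed=2)
        img, truth = render_scene(spec)
        mask = threshold_segment(to_gray(img), ThresholdSpec(t=120))
        contours = filter_marker_contours(find_contours(mask, min_pixels=20))
        with pytest.raises(LineExtractionError, match="edge mask"):
            extract_marker_axes(contours, method="hough", edges=None)


class TestLine2D:
    def test_intersection(self):
        l1 = Line2D(point=(0, 0), direction=(1, 0))
        l2 = Line2D(point=(3, -1), direction=(0, 1))
        assert np.allclose(l1.intersection(l2), (3, 0))

    def test_parallel_intersection_fails(self):
        l1 = Line2D(point=(0, 0), direction=(1, 0))
        l2 = Line2D(point=(0, 5), direction=(-1, 0))
        with pytest.raises(LineExtractionError, match="parallel"):
            l1.intersection(l2)

    def test_hough_normal_form_conversion(self):
        hl = HoughLine(rho=5.0, theta_deg=0.0, votes=10)
        line = hl.to_line()
        # x cos0 + y sin0 = 5 is the vertical line x = 5
        assert np.allclose(line.foot((0.0, 7.0)), (5.0, 7.0))
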