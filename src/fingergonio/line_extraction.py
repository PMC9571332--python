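"""Straight-line extraction from marker edges.

Two routes produce per-marker line descriptions:

* **Canny + Hough** — a multi-stage edge detector (Gaussian smoothing, Sobel
  gradients, gradient magnitude/direction with the direction quantized to
  0/45/90/135 degrees, non-maximum suppression along the quantized
  direction, two-threshold hysteresis linking) followed by a standard
  rho-theta Hough accumulator (x cos(theta) + y sin(theta) = rho).  Each
  marker contributes two near-parallel long-edge lines, one on each side;
  the side facing the bend of the finger chain is labelled *inner*, the
  other *outer*.
* **Least-squares fit** — the closed-form slope/intercept solution fitted to
  all contour points of a marker, yielding its centerline directly.  When
  the points are more vertical than horizontal the regression is performed
  as x on y to avoid the vertical-line blow-up, and the axis convention is
  recorded.

All image coordinates are (x, y) = (column, row), origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import LineExtractionError
from .segmentation import BinaryMask, MarkerContour

__all__ = [
    "HoughLine",
    "LineFit",
    "Line2D",
    "MarkerAxis",
    "canny",
    "quantize_gradient_direction",
    "hough_lines",
    "lsq_fit_line",
    "extract_marker_axes",
]


# ---------------------------------------------------------------------------
# line representations


@dataclass(frozen=True)
class HoughLine:
    """A line in normal form x cos(theta) + y sin(theta) = rho.

    ``rho`` in pixels (signed), ``theta_deg`` in [0, 180), ``votes`` the
    accumulator count of the detected peak.
    """

    rho: float
    theta_deg: float
    votes: int

    def to_line(self) -> "Line2D":
        th = np.deg2rad(self.theta_deg)
        n = np.array([np.cos(th), np.sin(th)])
        return Line2D(point=self.rho * n, direction=np.array([-n[1], n[0]]))


@dataclass(frozen=True)
class LineFit:
    """Closed-form least-squares line.

    ``axis == 'y-on-x'``: y = a x + b, loss sum (a x_i + b - y_i)^2.
    ``axis == 'x-on-y'``: x = a y + b (used when the points are more
    vertical than horizontal).  ``residual`` is the value of the loss.
    """

    a: float
    b: float
    axis: Literal["y-on-x", "x-on-y"]
    residual: float

    def to_line(self) -> "Line2D":
        if self.axis == "y-on-x":
            p = np.array([0.0, self.b])
            d = np.array([1.0, self.a])
        else:
            p = np.array([self.b, 0.0])
            d = np.array([self.a, 1.0])
        return Line2D(point=p, direction=d / np.linalg.norm(d))


@dataclass(frozen=True)
class Line2D:
    """Infinite line as point + unit direction; geometry workhorse."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise LineExtractionError("line direction must be nonzero")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)

    @property
    def normal(self) -> np.ndarray:
        d = self.direction
        return np.array([-d[1], d[0]])

    @property
    def angle_deg(self) -> float:
        """Direction angle mod 180 in [0, 180)."""
        a = np.degrees(np.arctan2(self.direction[1], self.direction[0]))
        return float(a % 180.0)

    def foot(self, pts: np.ndarray) -> np.ndarray:
        """Orthogonal projection of point(s) onto the line."""
        pts = np.asarray(pts, dtype=float)
        rel = pts - self.point
        t = rel @ self.direction
        return self.point + np.outer(np.atleast_1d(t), self.direction).reshape(
            pts.shape
        )

    def distance(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return np.abs((pts - self.point) @ self.normal)

    def intersection(self, other: "Line2D") -> np.ndarray:
        """Intersection point; raises for (near-)parallel lines."""
        a = np.column_stack([self.direction, -other.direction])
        det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
        if abs(det) < 1e-12:
            raise LineExtractionError("lines are parallel; no intersection")
        t = np.linalg.solve(a, other.point - self.point)
        return self.point + t[0] * self.direction

    def oriented(self, reference: np.ndarray) -> "Line2D":
        """Copy with direction flipped, if needed, to align with reference."""
        if float(np.dot(self.direction, reference)) < 0:
            return Line2D(self.point, -self.direction)
        return self


def angle_gap_deg(a: float, b: float) -> float:
    """Circular distance between two undirected line angles (mod 180)."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


# ---------------------------------------------------------------------------
# Canny edge detection


def quantize_gradient_direction(theta_deg: np.ndarray) -> np.ndarray:
    """Quantize gradient angles to the 4-set {0, 45, 90, 135} degrees.

    Input may span (-180, 180]; directions are taken mod 180 and mapped to
    the nearest of the four bins (157.5..180 wraps to 0).
    """
    a = np.asarray(theta_deg, dtype=float) % 180.0
    return (np.round(a / 45.0).astype(int) % 4) * 45


# per-bin neighbour offsets (dr, dc) for non-maximum suppression
_NMS_OFFSETS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def canny(
    gray: np.ndarray,
    sigma: float = 1.4,
    low: float = 50.0,
    high: float = 150.0,
) -> np.ndarray:
    """Multi-stage edge detector returning a boolean edge mask.

    Stages: Gaussian noise reduction (``sigma``), Sobel gradients, magnitude
    G = sqrt(Gx^2 + Gy^2) with direction theta = atan2(Gy, Gx) quantized to
    {0, 45, 90, 135} degrees, non-maximum suppression along the quantized
    direction, and hysteresis linking with the ``low``/``high`` thresholds
    (on the 0–255 intensity scale, Sobel-scaled).
    """
    if not (high >= low > 0):
        raise LineExtractionError(
            f"invalid thresholds: need high >= low > 0, got low={low}, "
            f"high={high}"
        )
    img = ndimage.gaussian_filter(np.asarray(gray, dtype=float), sigma)
    gx = ndimage.sobel(img, axis=1)
    gy = ndimage.sobel(img, axis=0)
    g = np.hypot(gx, gy)
    theta = np.degrees(np.arctan2(gy, gx))
    q = quantize_gradient_direction(theta)

    # non-maximum suppression: keep pixels not dominated by either neighbour
    # along the (quantized) gradient direction
    padded = np.pad(g, 1, constant_values=-np.inf)
    keep = np.zeros_like(g, dtype=bool)
    rows, cols = np.indices(g.shape)
    for ang, (dr, dc) in _NMS_OFFSETS.items():
        sel = q == ang
        r, c = rows[sel] + 1, cols[sel] + 1
        fwd = padded[r + dr, c + dc]
        bwd = padded[r - dr, c - dc]
        # ">= fwd and > bwd" thins 2-pixel plateaus deterministically
        keep[sel] = (g[sel] >= fwd) & (g[sel] > bwd)
    nms = np.where(keep, g, 0.0)

    strong = nms >= high
    weak = nms >= low
    edges = ndimage.binary_propagation(
        strong, mask=weak, structure=np.ones((3, 3), dtype=bool)
    )
    return edges


# ---------------------------------------------------------------------------
# Hough transform


def _accumulate(
    xs: np.ndarray, ys: np.ndarray, shape: tuple[int, int],
    rho_res: float, theta_res: float,
):
    thetas = np.arange(0.0, 180.0, theta_res)
    diag = float(np.hypot(shape[0], shape[1]))
    n_half = int(np.ceil(diag / rho_res))
    n_rho = 2 * n_half + 1
    acc = np.zeros((n_rho, len(thetas)), dtype=np.int64)
    cos = np.cos(np.deg2rad(thetas))
    sin = np.sin(np.deg2rad(thetas))
    for j in range(len(thetas)):
        rho = xs * cos[j] + ys * sin[j]
        idx = np.round(rho / rho_res).astype(int) + n_half
        acc[:, j] += np.bincount(idx, minlength=n_rho)
    rhos = (np.arange(n_rho) - n_half) * rho_res
    return acc, rhos, thetas


def hough_lines(
    edges: np.ndarray | BinaryMask,
    rho_res: float = 1.0,
    theta_res: float = 1.0,
    vote_threshold: int = 10,
) -> list[HoughLine]:
    """Standard rho-theta Hough transform over an edge mask.

    The accumulator spans theta in [0, 180) degrees at ``theta_res`` and
    signed rho at ``rho_res``.  Peaks are accumulator cells that are local
    maxima over their 3x3 neighbourhood with at least ``vote_threshold``
    votes, sorted by votes descending, ties broken by (theta, rho)
    ascending.  An empty mask yields an empty list.
    """
    if rho_res <= 0 or theta_res <= 0:
        raise LineExtractionError("rho_res and theta_res must be positive")
    if isinstance(edges, BinaryMask):
        e = edges.is_target
    else:
        e = np.asarray(edges, dtype=bool)
    ys, xs = np.nonzero(e)
    if len(xs) == 0:
        return []
    acc, rhos, thetas = _accumulate(
        xs.astype(float), ys.astype(float), e.shape, rho_res, theta_res
    )
    local_max = acc == ndimage.maximum_filter(acc, size=3, mode="constant")
    peaks = np.argwhere(local_max & (acc >= vote_threshold))
    lines = [
        HoughLine(rho=float(rhos[i]), theta_deg=float(thetas[j]),
                  votes=int(acc[i, j]))
        for i, j in peaks
    ]
    lines.sort(key=lambda l: (-l.votes, l.theta_deg, l.rho))
    return lines


# ---------------------------------------------------------------------------
# least-squares line fitting


def lsq_fit_line(
    points: Sequence,
    axis: Literal["auto", "y-on-x", "x-on-y"] = "auto",
) -> LineFit:
    """Closed-form least-squares line through 2-D points.

    Fits y = a x + b with
    a = (N sum(x y) - sum(x) sum(y)) / (N sum(x^2) - sum(x)^2),
    b = (sum(x^2) sum(y) - sum(x) sum(x y)) / (N sum(x^2) - sum(x)^2).
    With ``axis='auto'`` (default) the regression is performed as
    x = a y + b instead whenever the x-variance is smaller than the
    y-variance — steep point clouds are fitted in the better-conditioned
    direction and vertical lines do not blow up; the axis flag records the
    choice.  Forcing an axis evaluates that form regardless.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise LineExtractionError("need at least 2 points of shape (N, 2)")
    if np.allclose(pts, pts[0], atol=1e-12):
        raise LineExtractionError("all points identical; line undefined")
    x, y = pts[:, 0], pts[:, 1]
    if axis == "auto":
        axis = "y-on-x" if np.var(x) >= np.var(y) else "x-on-y"
    if axis == "y-on-x":
        u, w = x, y
    else:
        u, w = y, x
    n = float(len(pts))
    su, sw = u.sum(), w.sum()
    suu, suw = (u * u).sum(), (u * w).sum()
    den = n * suu - su * su
    if abs(den) < 1e-12:
        raise LineExtractionError("degenerate point configuration for fit")
    a = (n * suw - su * sw) / den
    b = (suu * sw - su * suw) / den
    residual = float(((a * u + b - w) ** 2).sum())
    return LineFit(a=float(a), b=float(b), axis=axis, residual=residual)


# ---------------------------------------------------------------------------
# marker axes


@dataclass(frozen=True)
class MarkerAxis:
    """Per-marker line geometry, oriented proximal -> distal.

    ``inner``/``outer`` are the long-edge lines on the concave/convex side
    of the finger chain (identical in least-squares mode).  ``centerline``
    is their average (or the single fitted line).  ``head``/``tail`` are the
    proximal and distal endpoints of the centerline segment.
    """

    index: int
    inner: Line2D
    outer: Line2D
    centerline: Line2D
    head: np.ndarray
    tail: np.ndarray
    inner_raw: object = None  # HoughLine or LineFit diagnostics
    outer_raw: object = None

    @property
    def direction(self) -> np.ndarray:
        return self.centerline.direction

    @property
    def inner_dir(self) -> np.ndarray:
        return self.inner.oriented(self.direction).direction

    @property
    def outer_dir(self) -> np.ndarray:
        return self.outer.oriented(self.direction).direction

    @property
    def angular_gap_deg(self) -> float:
        return angle_gap_deg(self.inner.angle_deg, self.outer.angle_deg)


def _chain_tangents(centroids: np.ndarray) -> np.ndarray:
    """Unit tangent of the chain at each marker (central differences)."""
    n = len(centroids)
    t = np.zeros((n, 2))
    for i in range(n):
        a = centroids[max(i - 1, 0)]
        b = centroids[min(i + 1, n - 1)]
        t[i] = b - a
    norms = np.linalg.norm(t, axis=1, keepdims=True)
    return t / norms


def _bend_signs(centroids: np.ndarray) -> np.ndarray:
    """Mean z-cross of adjacent segment tangents at each marker; the sign
    says which side of the chain is concave (0 for a straight chain)."""
    seg = np.diff(centroids, axis=0)
    seg = seg / np.linalg.norm(seg, axis=1, keepdims=True)
    z = seg[:-1, 0] * seg[1:, 1] - seg[:-1, 1] * seg[1:, 0]  # joints 0..n-2
    n = len(centroids)
    s = np.zeros(n)
    for i in range(n):
        adj = [j for j in (i - 1, i) if 0 <= j < len(z)]
        s[i] = np.mean(z[adj]) if adj else 0.0
    return s


def _pca_axis(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _endpoints(line: Line2D, contour_pts: np.ndarray):
    proj = (contour_pts - line.point) @ line.direction
    head = line.point + proj.min() * line.direction
    tail = line.point + proj.max() * line.direction
    return head, tail


def _refine_on_edges(
    line: Line2D, edge_pts: np.ndarray, corridor: float
) -> Line2D | None:
    """Least-squares re-fit of a Hough line to the edge pixels within a
    perpendicular corridor of it; None when too few pixels support it."""
    d = line.distance(edge_pts).ravel()
    sel = edge_pts[d <= corridor]
    if len(sel) < 5:
        return None
    try:
        return lsq_fit_line(sel).to_line()
    except LineExtractionError:
        return None


def extract_marker_axes(
    contours: Sequence[MarkerContour],
    method: Literal["hough", "lsq"] = "hough",
    edges: np.ndarray | None = None,
    cfg=None,
    layout: Literal["chain", "fan"] = "chain",
) -> list[MarkerAxis]:
    """Build the per-marker axis (inner/outer/centerline) for 4 ordered
    marker contours.

    ``hough`` mode needs an edge mask: for each marker, lines are detected
    in the dilated bounding region of its contour, kept when near-parallel
    to the contour's elongation axis, and the best-vote line on each side of
    the centroid becomes one long edge; inner/outer labels follow the bend
    of the chain (image-left of the chain direction for a straight chain).
    ``lsq`` mode fits one centerline to all contour points and duplicates it
    as inner = outer.

    ``layout`` controls direction orientation: ``chain`` (flexion) orients
    each marker along the centroid chain; ``fan`` (abduction, markers on
    adjacent fingers radiating from the palm) orients marker 0 along the
    chain and each subsequent marker consistently with its predecessor,
    since a wide fan's centroid chord can be near-perpendicular to the
    marker axes.
    """
    from .config import PipelineConfig

    cfg = cfg or PipelineConfig()
    if method == "hough" and edges is None:
        raise LineExtractionError("hough mode requires an edge mask")
    centroids = np.array([c.centroid for c in contours])
    tangents = _chain_tangents(centroids)
    bends = _bend_signs(centroids)

    axes: list[MarkerAxis] = []
    prev_dir: np.ndarray | None = None
    for i, contour in enumerate(contours):
        t = tangents[i]
        elong = _pca_axis(contour.points)
        ref = t if (layout == "chain" or prev_dir is None) else prev_dir
        if float(np.dot(elong, ref)) < 0:
            elong = -elong
        prev_dir = elong
        if method == "lsq":
            fit = lsq_fit_line(contour.points)
            line = fit.to_line().oriented(elong)
            head, tail = _endpoints(line, contour.points)
            axes.append(
                MarkerAxis(index=i, inner=line, outer=line, centerline=line,
                           head=head, tail=tail,
                           inner_raw=fit, outer_raw=fit)
            )
            continue

        inner_l, outer_l, raw_in, raw_out = _marker_edge_lines(
            contour, edges, elong, t, bends[i], cfg
        )
        # anchor the centerline at the region centroid (sub-pixel accurate
        # from averaging all region pixels; the rectangle's centroid lies
        # on its long axis), direction from the two edge lines
        center = Line2D(
            point=contour.centroid,
            direction=(inner_l.oriented(elong).direction
                       + outer_l.oriented(elong).direction),
        )
        gap = angle_gap_deg(inner_l.angle_deg, outer_l.angle_deg)
        if gap > cfg.measure.near_parallel_bound_deg:
            raise LineExtractionError(
                f"marker {i}: inner/outer edge lines diverge by "
                f"{gap:.1f} deg (> {cfg.measure.near_parallel_bound_deg})"
            )
        head, tail = _endpoints(center, contour.points)
        axes.append(
            MarkerAxis(index=i, inner=inner_l, outer=outer_l,
                       centerline=center, head=head, tail=tail,
                       inner_raw=raw_in, outer_raw=raw_out)
        )
    return axes


def _marker_edge_lines(contour, edges, elong, tangent, bend, cfg):
    """Detect the two long-edge lines of one marker in its edge
    neighbourhood and label them (inner, outer)."""
    x0, y0, x1, y1 = contour.bbox
    pad = cfg.hough.bbox_pad_px
    r0 = max(int(np.floor(y0)) - pad, 0)
    c0 = max(int(np.floor(x0)) - pad, 0)
    r1 = min(int(np.ceil(y1)) + pad + 1, edges.shape[0])
    c1 = min(int(np.ceil(x1)) + pad + 1, edges.shape[1])
    crop = np.asarray(edges, dtype=bool)[r0:r1, c0:c1]

    proj = (contour.points - contour.centroid) @ elong
    major_len = float(proj.max() - proj.min())
    votes_needed = cfg.hough.vote_threshold or max(
        int(round(0.5 * major_len)), 5
    )
    lines = hough_lines(crop, cfg.hough.rho_res_px, cfg.hough.theta_res_deg,
                        votes_needed)
    if not lines:
        raise LineExtractionError(
            f"marker {contour.centroid}: no Hough lines above "
            f"{votes_needed} votes"
        )
    offset = np.array([c0, r0], dtype=float)
    elong_angle = float(np.degrees(np.arctan2(elong[1], elong[0])) % 180.0)

    best = {+1: None, -1: None}
    for hl in lines:
        if angle_gap_deg(hl.theta_deg, (elong_angle + 90.0) % 180.0) > \
                cfg.measure.near_parallel_bound_deg:
            continue
        geo = hl.to_line()
        geo = Line2D(point=geo.point + offset, direction=geo.direction)
        # side of the line relative to the marker centroid
        v = geo.foot(contour.centroid) - contour.centroid
        if np.linalg.norm(v) < cfg.hough.min_edge_offset_px:
            continue  # runs through the middle; not a long edge
        side = int(np.sign(tangent[0] * v[1] - tangent[1] * v[0]))
        if side == 0:
            continue
        if best[side] is None:
            best[side] = (geo, hl)
    if best[+1] is None or best[-1] is None:
        raise LineExtractionError(
            f"marker at {np.round(contour.centroid, 1)}: could not find a "
            f"long-edge line on both sides (found sides: "
            f"{[s for s, v in best.items() if v is not None]})"
        )
    if cfg.hough.refine_lines:
        ys, xs = np.nonzero(np.asarray(edges, dtype=bool)[r0:r1, c0:c1])
        pts = np.column_stack([xs + c0, ys + r0]).astype(float)
        for side in (+1, -1):
            geo, hl = best[side]
            refined = _refine_on_edges(geo, pts, cfg.hough.refine_corridor_px)
            if refined is not None:
                best[side] = (refined, hl)

    # bend > 0 means the chain turns toward cross(t, .) > 0; that side is
    # concave, i.e. "inner".  Straight chain: image-left of the direction.
    inner_side = +1 if bend > 1e-3 else (-1 if bend < -1e-3 else +1)
    (inner_geo, inner_raw) = best[inner_side]
    (outer_geo, outer_raw) = best[-inner_side]
    return inner_geo, outer_geo, inner_raw, outer_raw
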