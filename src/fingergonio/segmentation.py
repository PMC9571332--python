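"""Marker segmentation: HSV color gating, gray thresholding, contour tracing.

Two independent routes isolate the four blue rectangular joint markers:

* **HSV gating** — convert RGB to HSV and keep pixels whose channels fall in
  closed intervals.  H is stored as degrees/2 in [0, 180) (so pure blue, 240
  degrees, is stored as 120), S and V are scaled to [0, 255]; the default
  gates are H 100–130, S 150–255, V 130–255, which bracket the marker blue.
* **Gray thresholding** — BT.601 luma conversion followed by a fixed or
  automatic (Otsu) threshold; the markers are dark against a skin-toned
  background, so the target label is the low side.

Binary masks carry explicit target/background labels (default target = 0,
background = 255).  Connected target regions are traced into closed boundary
contours (Moore-neighbour tracing, 8-connectivity, Jacob's stopping
criterion) and the four marker contours are selected by area similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import SegmentationError

__all__ = [
    "BinaryMask",
    "ThresholdSpec",
    "MarkerContour",
    "rgb_to_hsv",
    "hsv_in_range",
    "to_gray",
    "auto_threshold",
    "threshold_segment",
    "find_contours",
    "filter_marker_contours",
    "order_along_chain",
]

DEFAULT_HSV_LO = (100, 150, 130)
DEFAULT_HSV_HI = (130, 255, 255)

# BT.601 luma weights; the grayscale formula is a package choice.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class BinaryMask:
    """Two-valued image with explicit target (A) and background labels."""

    values: np.ndarray
    target: int = 0
    background: int = 255

    def __post_init__(self):
        v = np.asarray(self.values)
        if self.target == self.background:
            raise SegmentationError("target and background labels must differ")
        extra = set(np.unique(v)) - {self.target, self.background}
        if extra:
            raise SegmentationError(f"mask contains foreign values: {extra}")
        object.__setattr__(self, "values", v)

    @property
    def is_target(self) -> np.ndarray:
        """Boolean array, True where the pixel carries the target label."""
        return self.values == self.target

    @property
    def shape(self):
        return self.values.shape

    @classmethod
    def from_bool(cls, b: np.ndarray, target: int = 0, background: int = 255):
        b = np.asarray(b, dtype=bool)
        return cls(np.where(b, target, background).astype(np.int32),
                   target, background)


@dataclass(frozen=True)
class ThresholdSpec:
    """Gray threshold T with the two output labels of the pointwise rule
    g = background where f > T, g = target where f <= T."""

    t: int
    target: int = 0
    background: int = 255
    mode: str = "fixed"  # "fixed" | "automatic"

    def __post_init__(self):
        if not (0 <= self.t <= 255):
            raise SegmentationError(f"threshold T={self.t} outside [0, 255]")
        if self.target == self.background:
            raise SegmentationError("target and background labels must differ")


@dataclass(frozen=True)
class MarkerContour:
    """Closed outer boundary of one connected target region.

    ``points`` are ordered boundary pixel centers as (x, y) = (col, row);
    the first point is adjacent to the last.  ``area`` is the shoelace area
    of that polygon; ``pixel_count`` the number of region pixels.  The two
    differ by roughly half the boundary length (pixel-center convention).
    """

    points: np.ndarray
    area: float
    pixel_count: int
    centroid: np.ndarray  # (x, y) mean of region pixels

    def __post_init__(self):
        p = np.asarray(self.points, dtype=float)
        if len(p) < 3:
            raise SegmentationError("contour needs at least 3 boundary points")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "centroid",
                           np.asarray(self.centroid, dtype=float))

    @property
    def bbox(self):
        """(x0, y0, x1, y1) inclusive bounds of the boundary points."""
        mn = self.points.min(axis=0)
        mx = self.points.max(axis=0)
        return (mn[0], mn[1], mx[0], mx[1])


# ---------------------------------------------------------------------------
# color conversion and gating


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to HSV in the storage convention
    H in [0, 180) (degrees / 2), S and V in [0, 255].

    V = max(R, G, B); S = (V - min) / V scaled (0 where V = 0); H from the
    standard three-branch hue formula with negative hues wrapped by +360.
    Achromatic pixels (V = min) carry H = 0.
    """
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] != 3:
        raise SegmentationError("expected an (H, W, 3) RGB image")
    rgb = a.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    v = rgb.max(axis=-1)
    mn = rgb.min(axis=-1)
    c = v - mn
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, c / v * 255.0, 0.0)
        cs = np.where(c > 0, c, 1.0)  # avoid /0; masked out below
        h_deg = np.select(
            [c == 0, v == r, v == g],
            [0.0,
             60.0 * (g - b) / cs,
             120.0 + 60.0 * (b - r) / cs],
            default=240.0 + 60.0 * (r - g) / cs,
        )
    h_deg = np.where(h_deg < 0, h_deg + 360.0, h_deg)
    out = np.stack([h_deg / 2.0, s, v], axis=-1)
    return out


def hsv_in_range(hsv: np.ndarray, lo=DEFAULT_HSV_LO, hi=DEFAULT_HSV_HI,
                 target: int = 0, background: int = 255) -> BinaryMask:
    """Mark pixels whose H, S, V all lie in the closed intervals [lo, hi].

    Defaults are the marker-blue gates H 100–130, S 150–255, V 130–255.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(lo > hi):
        raise SegmentationError(f"inverted HSV bounds: lo={lo} hi={hi}")
    inside = np.all((hsv >= lo) & (hsv <= hi), axis=-1)
    return BinaryMask.from_bool(inside, target, background)


def to_gray(img: np.ndarray) -> np.ndarray:
    """BT.601 luma grayscale (0.299 R + 0.587 G + 0.114 B), rounded uint8."""
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] != 3:
        raise SegmentationError("expected an (H, W, 3) RGB image")
    g = a.astype(np.float64) @ _LUMA
    return np.clip(np.round(g), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# thresholding


def _between_class_variance(hist: np.ndarray) -> np.ndarray:
    """sigma_b^2(T) for classes f <= T vs f > T, T = 0..255."""
    p = hist / hist.sum()
    levels = np.arange(256)
    w0 = np.cumsum(p)
    mu_cum = np.cumsum(p * levels)
    mu_t = mu_cum[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_t - mu_cum) / w1
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    return sigma_b


def auto_threshold(gray: np.ndarray) -> ThresholdSpec:
    """Otsu threshold: T maximizing the between-class variance over all 256
    candidate levels (smallest maximizer on ties).

    Raises on constant images, which must use a fixed threshold instead.
    """
    g = np.asarray(gray)
    hist = np.bincount(g.ravel().astype(np.int64), minlength=256)[:256]
    if np.count_nonzero(hist) < 2:
        raise SegmentationError(
            "image has a single gray level; automatic thresholding is "
            "undefined — supply a fixed-T ThresholdSpec"
        )
    sigma_b = _between_class_variance(hist)
    t = int(np.argmax(sigma_b))
    return ThresholdSpec(t=t, mode="automatic")


def threshold_segment(gray: np.ndarray, spec: ThresholdSpec) -> BinaryMask:
    """Pointwise rule g = background where f > T, g = target where f <= T,
    applied by raster scans in both directions; the two passes are compared
    and must agree (the rule is pointwise, so a mismatch is an internal
    error)."""
    g = np.asarray(gray)
    forward = np.where(g > spec.t, spec.background, spec.target)
    backward = np.where(g[::-1, ::-1] > spec.t, spec.background,
                        spec.target)[::-1, ::-1]
    if not np.array_equal(forward, backward):  # pragma: no cover
        raise SegmentationError(
            "dual-direction raster scans disagree (internal error)"
        )
    return BinaryMask(forward.astype(np.int32), spec.target, spec.background)


# ---------------------------------------------------------------------------
# contour tracing

# Moore neighbourhood in clockwise order, as (dr, dc), starting due West.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_boundary(region: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Moore-neighbour boundary trace of one 8-connected region.

    ``region`` is a padded boolean array; ``start`` the lexicographically
    smallest (row, col) region pixel (so its West neighbour is outside the
    region).  From the current pixel the Moore neighbourhood is scanned
    clockwise starting just past the backtrack pixel; the trace stops when
    the (pixel, backtrack) state repeats, which closes the boundary exactly
    once.  Returns the boundary as (row, col) pixel centers.
    """
    p = start
    b = (start[0], start[1] - 1)  # West neighbour, outside region
    boundary = [p]
    seen = {(p, b)}
    while True:
        i0 = _MOORE.index((b[0] - p[0], b[1] - p[1]))
        nxt = None
        prev = b
        for k in range(1, 9):
            d = (i0 + k) % 8
            q = (p[0] + _MOORE[d][0], p[1] + _MOORE[d][1])
            if region[q]:
                nxt = q
                break
            prev = q
        if nxt is None:  # isolated pixel
            return np.asarray(boundary)
        p, b = nxt, prev
        if (p, b) in seen:
            break
        seen.add((p, b))
        boundary.append(p)
    if len(boundary) > 1 and boundary[0] == boundary[-1]:
        boundary.pop()
    return np.asarray(boundary)


def _shoelace(points_xy: np.ndarray) -> float:
    x = points_xy[:, 0]
    y = points_xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def find_contours(mask: BinaryMask, min_pixels: int = 1) -> list[MarkerContour]:
    """Trace the outer boundary of every 8-connected target region.

    Regions whose boundary has fewer than 3 points (single pixels, bare
    2-pixel dominoes) are dropped, as are regions below ``min_pixels``.
    An empty mask yields an empty list.
    """
    tgt = mask.is_target
    labels, n = ndimage.label(tgt, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    padded = np.pad(labels, 1)
    contours: list[MarkerContour] = []
    counts = np.bincount(labels.ravel())
    for lab in range(1, n + 1):
        if counts[lab] < max(min_pixels, 1):
            continue
        region = padded == lab
        rows, cols = np.nonzero(labels == lab)
        # lexicographically smallest boundary pixel (min row, then min col)
        i0 = np.lexsort((cols, rows))[0]
        start = (rows[i0] + 1, cols[i0] + 1)  # padded coords
        b = _trace_boundary(region, start)
        if len(b) < 3:
            continue
        pts_xy = np.column_stack([b[:, 1] - 1, b[:, 0] - 1]).astype(float)
        centroid = np.array([cols.mean(), rows.mean()])
        contours.append(
            MarkerContour(
                points=pts_xy,
                area=_shoelace(pts_xy),
                pixel_count=int(counts[lab]),
                centroid=centroid,
            )
        )
    return contours


# ---------------------------------------------------------------------------
# marker selection


def order_along_chain(
    centroids: np.ndarray, proximal_hint: np.ndarray | None = None
) -> np.ndarray:
    """Order points along the finger chain, proximal first.

    Finds the minimum-total-length open path through the points (exhaustive
    over orderings — there are only a handful of markers), robust for both
    straight and tightly curled chains.  Orientation: when
    ``proximal_hint`` (a pixel point on the proximal side, e.g. known from
    the rig layout) is given, the path starts at the end nearer to it;
    otherwise the end with the smaller projection on the sign-canonicalized
    first principal axis of the centroids (axis forced to positive x, or
    positive y when nearly vertical) comes first — i.e. the image-left end
    for a roughly horizontal chain.
    """
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    if n <= 2:
        order = np.arange(n)
    else:
        best, best_len = None, np.inf
        for perm in permutations(range(n)):
            if perm[0] > perm[-1]:
                continue  # each path counted once
            p = pts[list(perm)]
            length = np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
            if length < best_len - 1e-12:
                best, best_len = perm, length
        order = np.asarray(best)
    first, last = pts[order[0]], pts[order[-1]]
    if proximal_hint is not None:
        hint = np.asarray(proximal_hint, dtype=float)
        flip = np.linalg.norm(first - hint) > np.linalg.norm(last - hint)
    else:
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        if axis[0] < -1e-6 or (abs(axis[0]) <= 1e-6 and axis[1] < 0):
            axis = -axis
        pf, pl = (first - pts.mean(axis=0)) @ axis, \
            (last - pts.mean(axis=0)) @ axis
        flip = pf > pl + 1e-12 or (
            abs(pf - pl) <= 1e-12 and tuple(first) > tuple(last))
    return order[::-1] if flip else order


def filter_marker_contours(
    contours: Sequence[MarkerContour],
    expected: int = 4,
    tol: float = 0.25,
    proximal_hint: np.ndarray | None = None,
) -> list[MarkerContour]:
    """Select the ``expected`` marker contours by area similarity.

    Chooses the subset minimizing the relative area spread
    (max - min) / mean (exhaustive over subsets; for pathological masks with
    more than 16 contours only the 16 largest are considered).  Fails if
    fewer than ``expected`` contours exist or the best spread exceeds
    ``tol``.  The selection is returned ordered along the finger,
    proximal to distal.
    """
    if len(contours) < expected:
        raise SegmentationError(
            f"expected {expected} marker contours, found {len(contours)} "
            f"(areas: {[round(c.area, 1) for c in contours]})"
        )
    pool = sorted(contours, key=lambda c: -c.area)[:16]
    best, best_spread = None, np.inf
    for subset in combinations(range(len(pool)), expected):
        areas = np.array([pool[i].area for i in subset])
        spread = (areas.max() - areas.min()) / areas.mean()
        if spread < best_spread - 1e-12:
            best, best_spread = subset, spread
    if best_spread > tol:
        raise SegmentationError(
            f"no {expected}-subset of contours has relative area spread "
            f"<= {tol} (best {best_spread:.3f}; areas "
            f"{[round(c.area, 1) for c in pool]})"
        )
    chosen = [pool[i] for i in best]
    order = order_along_chain(np.array([c.centroid for c in chosen]),
                              proximal_hint=proximal_hint)
    return [chosen[i] for i in order]
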