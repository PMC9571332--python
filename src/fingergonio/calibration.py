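"""Planar camera calibration for metric measurement on a fixed detection plane.

The camera observes a fixed plane (the detection table the finger rests on).
For a plane, the full pinhole model collapses to a single 3x3 projective
mapping ``x ~ H X`` between world-plane coordinates ``X = (Wx, Wy, 1)`` in
millimetres and pixel coordinates ``x = (u, v, 1)``.  Once ``H`` is solved
from a handful of point correspondences, any pixel can be mapped back to the
plane (``X ~ H^-1 x``) and distances between image points can be reported in
millimetres.  The mapping is only valid while the plane-to-camera distance is
unchanged, so ``H`` is an explicit argument of every metric operation here —
there is no hidden global calibration state.

Pixel convention: 0-based, origin at the top-left corner, ``u`` = column,
``v`` = row.  World units are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import CalibrationError

__all__ = [
    "CorrespondenceSet",
    "PlanarHomography",
    "solve_homography",
    "world_to_pixel",
    "pixel_to_world",
    "world_distance",
    "read_correspondences_csv",
]

_COLLINEAR_TOL = 1e-8


@dataclass(frozen=True)
class CorrespondenceSet:
    """Paired pixel and world-plane points used to solve the homography."""

    pixels: np.ndarray  # (N, 2) float, (u, v)
    world: np.ndarray  # (N, 2) float, (Wx, Wy) in mm

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        w = np.asarray(self.world, dtype=float)
        if px.ndim != 2 or px.shape[1] != 2 or w.shape != px.shape:
            raise CalibrationError(
                "pixels and world must both be (N, 2) arrays of equal length"
            )
        if len(px) < 4:
            raise CalibrationError(
                f"at least 4 correspondences required, got {len(px)}"
            )
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "world", w)

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class PlanarHomography:
    """3x3 world-plane (mm) -> pixel mapping, defined up to scale.

    Normalized so ``h[2, 2] == 1`` whenever that entry is nonzero.
    ``reprojection_rms`` is the root-mean-square pixel residual on the
    correspondences the matrix was solved from (0 for exact constructions).
    """

    h: np.ndarray
    units: str = "mm"
    pixel_origin: str = "top-left-0-based"
    reprojection_rms: float = 0.0

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float)
        if h.shape != (3, 3):
            raise CalibrationError("homography must be 3x3")
        if not np.all(np.isfinite(h)):
            raise CalibrationError("homography contains non-finite entries")
        if abs(np.linalg.det(h)) < 1e-15:
            raise CalibrationError("homography is singular")
        if abs(h[2, 2]) > 1e-12:
            h = h / h[2, 2]
        object.__setattr__(self, "h", h)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.h)

    # -- serialization ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "h": [float(v) for v in self.h.ravel()],
            "units": self.units,
            "pixel_origin": self.pixel_origin,
            "reprojection_rms": float(self.reprojection_rms),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlanarHomography":
        d = json.loads(Path(path).read_text())
        return cls(
            h=np.asarray(d["h"], dtype=float).reshape(3, 3),
            units=d.get("units", "mm"),
            pixel_origin=d.get("pixel_origin", "top-left-0-based"),
            reprojection_rms=float(d.get("reprojection_rms", 0.0)),
        )

    @classmethod
    def identity(cls) -> "PlanarHomography":
        return cls(h=np.eye(3))


def _check_degenerate(corr: CorrespondenceSet) -> None:
    """Reject duplicate points and (for N == 4) collinear world triples."""
    for name, pts in (("pixel", corr.pixels), ("world", corr.world)):
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        iu = np.triu_indices(len(pts), k=1)
        dup = np.argwhere(d[iu] < 1e-9)
        if dup.size:
            i, j = iu[0][dup[0][0]], iu[1][dup[0][0]]
            raise CalibrationError(
                f"duplicate {name} points at indices {i} and {j}: {pts[i]}"
            )
    if len(corr) == 4:
        from itertools import combinations

        for i, j, k in combinations(range(4), 3):
            a, b, c = corr.world[[i, j, k]]
            area2 = abs((b - a)[0] * (c - a)[1] - (b - a)[1] * (c - a)[0])
            scale = max(np.abs(corr.world).max(), 1.0)
            if area2 < _COLLINEAR_TOL * scale**2:
                raise CalibrationError(
                    f"world points {i}, {j}, {k} are collinear: "
                    f"{a}, {b}, {c}"
                )


def _normalizing_transform(pts: np.ndarray) -> np.ndarray:
    """Similarity transform taking points to centroid 0, RMS distance sqrt(2)."""
    c = pts.mean(axis=0)
    rms = np.sqrt(((pts - c) ** 2).sum(axis=1).mean())
    s = np.sqrt(2.0) / rms if rms > 1e-12 else 1.0
    return np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])


def solve_homography(corr: CorrespondenceSet) -> PlanarHomography:
    """Solve the world->pixel homography by the normalized direct linear
    transform (Hartley normalization on both point sets, SVD null space).

    Raises :class:`CalibrationError` on degenerate configurations, naming the
    offending points.  The returned matrix carries the RMS reprojection
    residual over the input pairs.
    """
    _check_degenerate(corr)
    Tp = _normalizing_transform(corr.pixels)
    Tw = _normalizing_transform(corr.world)
    ph = np.column_stack([corr.pixels, np.ones(len(corr))]) @ Tp.T
    wh = np.column_stack([corr.world, np.ones(len(corr))]) @ Tw.T

    rows = []
    for (wx, wy, _), (u, v, _) in zip(wh, ph):
        rows.append([wx, wy, 1, 0, 0, 0, -u * wx, -u * wy, -u])
        rows.append([0, 0, 0, wx, wy, 1, -v * wx, -v * wy, -v])
    A = np.asarray(rows)
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-12 * s[0]:
        raise CalibrationError(
            "correspondence configuration is degenerate (rank-deficient "
            "design matrix); check for collinear or duplicated points"
        )
    hn = vt[-1].reshape(3, 3)
    h = np.linalg.inv(Tp) @ hn @ Tw
    H = PlanarHomography(h=h)

    proj = world_to_pixel(H, corr.world)
    rms = float(np.sqrt(((proj - corr.pixels) ** 2).sum(axis=1).mean()))
    return PlanarHomography(h=H.h, reprojection_rms=rms)


def _apply(m: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    homog = np.column_stack([pts, np.ones(len(pts))]) @ m.T
    w = homog[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise CalibrationError(
            "point maps to the line at infinity (homogeneous w ~ 0)"
        )
    return homog[:, :2] / w[:, None]


def world_to_pixel(h: PlanarHomography, world_pts) -> np.ndarray:
    """Map world-plane mm point(s) to pixel coordinates."""
    out = _apply(h.h, world_pts)
    return out if np.asarray(world_pts).ndim == 2 else out[0]


def pixel_to_world(h: PlanarHomography, pixel_pts) -> np.ndarray:
    """Map pixel point(s) to world-plane mm coordinates (inverse mapping)."""
    out = _apply(h.inverse, pixel_pts)
    return out if np.asarray(pixel_pts).ndim == 2 else out[0]


def world_distance(h: PlanarHomography, p1, p2) -> float:
    """Euclidean mm distance between two pixel points mapped to the plane."""
    w1 = pixel_to_world(h, np.asarray(p1, dtype=float))
    w2 = pixel_to_world(h, np.asarray(p2, dtype=float))
    return float(np.linalg.norm(w1 - w2))


def read_correspondences_csv(path: str | Path) -> CorrespondenceSet:
    """Read a correspondence CSV with columns ``u, v, Wx, Wy`` (mm)."""
    df = pd.read_csv(path)
    missing = {"u", "v", "Wx", "Wy"} - set(df.columns)
    if missing:
        raise CalibrationError(
            f"correspondence CSV missing columns: {sorted(missing)}"
        )
    return CorrespondenceSet(
        pixels=df[["u", "v"]].to_numpy(float),
        world=df[["Wx", "Wy"]].to_numpy(float),
    )
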