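"""Synthetic scene rendering with exact ground truth.

No image corpus ships with the measurement protocol, so testing runs on
rendered stand-ins that emulate its acquisition rig: four blue rectangular
markers (default 10 mm long, 1.5/2/2.5 mm wide) laid out by the forward
kinematics of a planar four-segment finger chain over a skin-toned
background, imaged at a fixed scale (default 0.1 mm per pixel), under a
multiplicative illumination ramp (high/medium/low angle lighting mapped to
ramp strengths 0.05/0.2/0.4), a small optical blur, and Gaussian sensor
noise.  All geometry — marker corners, joint angles, phalanx lengths, the
pixel<->mm homography — is computed exactly *before* rasterization, so the
emitted truth carries no rasterization error.  Rendering is deterministic
given the seed.

Angle convention: interior angles, 180 degrees = straight.  The chain bends
consistently to one side (positive in-image rotation).  Abduction scenes
instead fan the four markers out of a common base point by the given
pairwise spread angles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

from .calibration import PlanarHomography
from .errors import FingergonioError

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "render_scene",
    "render_pose_battery",
    "DEFAULT_POSES",
    "DEFAULT_SCALES",
]

#: Knuckle-hold poses (MCP, PIP, DIP) used throughout the validation study.
DEFAULT_POSES: tuple[tuple[float, float, float], ...] = (
    (145.0, 110.0, 115.0),
    (160.0, 130.0, 110.0),
    (150.0, 165.0, 130.0),
)

#: Marker widths (mm) compared in the scale study.
DEFAULT_SCALES: tuple[float, ...] = (1.5, 2.0, 2.5)

_ILLUMINATION_RAMP = {"high": 0.05, "medium": 0.2, "low": 0.4}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered scene.

    ``angles`` are flexion interior angles (MCP, PIP, DIP) in (0, 180];
    if ``abduction_angles`` is set the scene is an abduction fan instead.
    ``segment_lengths_mm`` are the spans carrying the four markers
    (dorsal hand, proximal, middle, distal); the middle two are the true
    proximal/middle phalanx lengths between joint centers.
    """

    angles: tuple[float, float, float] = (145.0, 110.0, 115.0)
    abduction_angles: tuple[float, float, float] | None = None
    marker_width_mm: float = 1.5
    marker_length_mm: float = 10.0
    segment_lengths_mm: tuple[float, float, float, float] = (30.0, 35.0,
                                                             22.0, 16.0)
    mm_per_px: float = 0.1
    marker_rgb: tuple[int, int, int] = (30, 60, 200)
    background_rgb: tuple[int, int, int] = (205, 170, 145)
    texture_amplitude: float = 3.0
    illumination: str = "high"
    noise_sigma: float = 2.0
    blur_sigma: float = 0.6
    margin_mm: float = 8.0
    canvas_px: tuple[int, int] | None = None  # (height, width), None = fit
    fan_radius_mm: float = 18.0
    base_angle_deg: float = 0.0  # heading of the first segment (in-plane
    # rotation of the whole scene)
    seed: int = 0

    def __post_init__(self):
        use = self.abduction_angles or self.angles
        for a in use:
            if not (0.0 < a <= 180.0):
                raise FingergonioError(
                    f"joint angle {a} outside (0, 180]")
        if self.mm_per_px <= 0 or self.marker_width_mm <= 0 \
                or self.marker_length_mm <= 0:
            raise FingergonioError("scales and marker sizes must be > 0")
        if self.illumination not in _ILLUMINATION_RAMP:
            raise FingergonioError(
                f"illumination must be one of {sorted(_ILLUMINATION_RAMP)}")


@dataclass(frozen=True)
class SceneTruth:
    """Exact scene geometry emitted alongside the rendered image."""

    spec: SceneSpec
    corners_mm: np.ndarray  # (4 markers, 4 corners, 2)
    corners_px: np.ndarray
    hinge_mm: np.ndarray  # (5, 2) chain hinge points (flexion) or base+tips
    hinge_px: np.ndarray
    angles: tuple[float, float, float]
    lengths_mm: tuple[float, float] | None  # (proximal, middle)
    homography: PlanarHomography  # world mm -> pixel

    def marker_directions_px(self) -> np.ndarray:
        """Unit long-axis direction of each marker, proximal -> distal."""
        c = self.corners_px
        d = (c[:, 1] - c[:, 0])
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def chain_angles_from_corners(self) -> np.ndarray:
        """Recompute the interior joint angles from the emitted marker
        corner geometry (independent of the spec angles)."""
        dirs = self.marker_directions_px()
        out = []
        for i in range(3):
            a, b = -dirs[i], dirs[i + 1]
            cos = np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)),
                          -1, 1)
            ang = float(np.degrees(np.arccos(cos)))
            if self.spec.abduction_angles is not None:
                ang = 180.0 - ang
            out.append(ang)
        return np.asarray(out)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": 1,
            "angles": list(self.angles),
            "lengths_mm": None if self.lengths_mm is None
            else list(self.lengths_mm),
            "corners_mm": self.corners_mm.tolist(),
            "corners_px": self.corners_px.tolist(),
            "hinge_mm": self.hinge_mm.tolist(),
            "hinge_px": self.hinge_px.tolist(),
            "homography": [float(v) for v in self.homography.h.ravel()],
            "spec": {
                "angles": list(self.spec.angles),
                "abduction_angles": None
                if self.spec.abduction_angles is None
                else list(self.spec.abduction_angles),
                "marker_width_mm": self.spec.marker_width_mm,
                "marker_length_mm": self.spec.marker_length_mm,
                "mm_per_px": self.spec.mm_per_px,
                "illumination": self.spec.illumination,
                "noise_sigma": self.spec.noise_sigma,
                "seed": self.spec.seed,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _rot(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    return np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])


def _flexion_geometry(spec: SceneSpec):
    """Hinge points and marker corners (mm) of the flexed chain."""
    hinges = [np.zeros(2)]
    direction = _rot(spec.base_angle_deg) @ np.array([1.0, 0.0])
    dirs = []
    for i, L in enumerate(spec.segment_lengths_mm):
        dirs.append(direction.copy())
        hinges.append(hinges[-1] + L * direction)
        if i < 3:  # bend at the joint following this segment
            direction = _rot(180.0 - spec.angles[i]) @ direction
    corners = []
    for i in range(4):
        center = 0.5 * (hinges[i] + hinges[i + 1])
        u = dirs[i]
        nvec = np.array([-u[1], u[0]])
        hl = 0.5 * spec.marker_length_mm
        hw = 0.5 * spec.marker_width_mm
        # corner order: head-left, tail-left, tail-right, head-right so
        # corners[1] - corners[0] is the long-axis direction
        corners.append([center - hl * u - hw * nvec,
                        center + hl * u - hw * nvec,
                        center + hl * u + hw * nvec,
                        center - hl * u + hw * nvec])
    return np.asarray(hinges), np.asarray(corners)


def _abduction_geometry(spec: SceneSpec):
    """Marker corners (mm) of four markers fanning out of a base point."""
    base = np.zeros(2)
    beta = 0.0
    corners, tips = [], [base]
    for i in range(4):
        u = _rot(beta) @ np.array([1.0, 0.0])
        nvec = np.array([-u[1], u[0]])
        center = base + (spec.fan_radius_mm
                         + 0.5 * spec.marker_length_mm) * u
        hl = 0.5 * spec.marker_length_mm
        hw = 0.5 * spec.marker_width_mm
        corners.append([center - hl * u - hw * nvec,
                        center + hl * u - hw * nvec,
                        center + hl * u + hw * nvec,
                        center - hl * u + hw * nvec])
        tips.append(center + hl * u)
        if i < 3:
            beta += spec.abduction_angles[i]
    return np.asarray(tips), np.asarray(corners)


def _rasterize_marker(img: np.ndarray, corners_px: np.ndarray,
                      color: np.ndarray, ss: int = 4) -> None:
    """Blend one marker rectangle into ``img`` with sub-pixel coverage
    computed on an ``ss`` x supersampled grid inside its bounding box."""
    h, w = img.shape[:2]
    r = corners_px[:, 1]
    c = corners_px[:, 0]
    r0 = max(int(np.floor(r.min())) - 2, 0)
    c0 = max(int(np.floor(c.min())) - 2, 0)
    r1 = min(int(np.ceil(r.max())) + 3, h)
    c1 = min(int(np.ceil(c.max())) + 3, w)
    bh, bw = (r1 - r0) * ss, (c1 - c0) * ss
    # sub-cell j has center (r0 - 0.5) + (j + 0.5)/ss in image coordinates
    rr = (r - (r0 - 0.5)) * ss - 0.5
    cc = (c - (c0 - 0.5)) * ss - 0.5
    sub = np.zeros((bh, bw), dtype=np.float64)
    pr, pc = _sk_polygon(rr, cc, shape=(bh, bw))
    sub[pr, pc] = 1.0
    cov = sub.reshape(r1 - r0, ss, c1 - c0, ss).mean(axis=(1, 3))
    patch = img[r0:r1, c0:c1]
    patch[...] = patch * (1 - cov[..., None]) + color * cov[..., None]


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render one scene; returns (uint8 RGB image, exact truth).

    Deterministic given ``spec.seed``: two renders of the same spec are
    bit-identical.  Raises when a fixed ``canvas_px`` cannot contain the
    markers.
    """
    if spec.abduction_angles is not None:
        hinges_mm, corners_mm = _abduction_geometry(spec)
        angles = tuple(float(a) for a in spec.abduction_angles)
        lengths = None
    else:
        hinges_mm, corners_mm = _flexion_geometry(spec)
        angles = tuple(float(a) for a in spec.angles)
        lengths = (float(spec.segment_lengths_mm[1]),
                   float(spec.segment_lengths_mm[2]))

    all_pts = corners_mm.reshape(-1, 2)
    origin = all_pts.min(axis=0) - spec.margin_mm
    s = spec.mm_per_px
    h_mat = np.array([[1 / s, 0, -origin[0] / s],
                      [0, 1 / s, -origin[1] / s],
                      [0, 0, 1.0]])
    homography = PlanarHomography(h=h_mat)

    corners_px = (corners_mm - origin) / s
    hinge_px = (hinges_mm - origin) / s
    extent = (all_pts.max(axis=0) - origin + spec.margin_mm) / s
    need_w, need_h = int(np.ceil(extent[0])), int(np.ceil(extent[1]))
    if spec.canvas_px is not None:
        ch, cw = spec.canvas_px
        if (corners_px[..., 0].max() >= cw - 1
                or corners_px[..., 1].max() >= ch - 1
                or corners_px.min() < 1):
            raise FingergonioError(
                f"markers fall outside the {ch}x{cw} canvas; needs at least "
                f"{need_h}x{need_w} — enlarge canvas_px or leave it None"
            )
        need_h, need_w = ch, cw

    rng = np.random.default_rng(spec.seed)
    img = np.empty((need_h, need_w, 3), dtype=np.float64)
    img[...] = np.asarray(spec.background_rgb, dtype=float)
    if spec.texture_amplitude > 0:
        tex = ndimage.gaussian_filter(
            rng.normal(0.0, spec.texture_amplitude, (need_h, need_w)), 3.0)
        img += tex[..., None]

    color = np.asarray(spec.marker_rgb, dtype=float)
    for i in range(4):
        _rasterize_marker(img, corners_px[i], color)

    ramp_k = _ILLUMINATION_RAMP[spec.illumination]
    cols = np.arange(need_w) / max(need_w - 1, 1)
    img *= ((1.0 - ramp_k) + ramp_k * cols)[None, :, None]

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (spec.blur_sigma,
                                            spec.blur_sigma, 0))
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = SceneTruth(
        spec=spec, corners_mm=corners_mm, corners_px=corners_px,
        hinge_mm=hinges_mm, hinge_px=hinge_px, angles=angles,
        lengths_mm=lengths, homography=homography,
    )
    return img, truth


def render_pose_battery(
    poses: Sequence[tuple[float, float, float]] = DEFAULT_POSES,
    scales: Sequence[float] = DEFAULT_SCALES,
    illuminations: Sequence[str] = ("high",),
    seed: int = 0,
    outdir: str | Path = ".",
    **spec_overrides,
) -> pd.DataFrame:
    """Render a pose x scale x illumination corpus to disk.

    Writes one PNG + truth JSON pair per combination and a manifest CSV
    listing files, poses, scales, lights, seeds and ground-truth angles.
    Deterministic naming; two runs with the same seed produce identical
    manifests.  Returns the manifest as a DataFrame.
    """
    poses = list(poses)
    scales = list(scales)
    if not poses or not scales or not list(illuminations):
        raise FingergonioError("poses, scales and illuminations must be "
                               "non-empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pi, pose in enumerate(poses):
        for scale in scales:
            for light in illuminations:
                spec = SceneSpec(angles=tuple(pose), marker_width_mm=scale,
                                 illumination=light, seed=seed,
                                 **spec_overrides)
                img, truth = render_scene(spec)
                stem = (f"scene_p{pi}_w{scale:g}mm_{light}_s{seed}")
                iio.imwrite(outdir / f"{stem}.png", img)
                truth.to_json(outdir / f"{stem}.truth.json")
                rows.append({
                    "file": f"{stem}.png", "truth": f"{stem}.truth.json",
                    "mcp": pose[0], "pip": pose[1], "dip": pose[2],
                    "scale_mm": scale, "light": light, "seed": seed,
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
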