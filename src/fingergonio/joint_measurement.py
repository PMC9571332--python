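"""Joint angles and phalanx lengths from marker axes.

Each adjacent pair of marker axes defines one joint.  In flexion mode the
two phalanx vectors point *away* from the shared joint, so a straight finger
reads 180 degrees and a flexed joint reads its goniometric interior angle.
The inner-edge lines give theta_in, the outer-edge lines theta_out, and the
reported joint angle is their mean, theta = (theta_out + theta_in) / 2; in
least-squares mode the two coincide.  Joints are labelled MCP, PIP, DIP from
proximal to distal.  Joint centers are the intersections of consecutive
marker centerlines, and phalanx lengths are world-plane distances between
consecutive joint centers when a calibration homography is supplied.

In abduction mode the markers sit on adjacent fingers fanning out from the
palm; the angle between the outward-pointing directions of each positional
pair is reported directly (no reversal), so spread angles of a few tens of
degrees come out as-is.

Four method variants cross the segmentation route {HSV, threshold} with the
line route {Hough inner/outer, least squares}; the threshold + Hough variant
is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .calibration import PlanarHomography, world_distance
from .config import PipelineConfig
from .errors import (
    LineExtractionError,
    MeasurementError,
    PipelineError,
    SegmentationError,
)
from .line_extraction import MarkerAxis, canny, extract_marker_axes
from .segmentation import (
    auto_threshold,
    filter_marker_contours,
    find_contours,
    hsv_in_range,
    rgb_to_hsv,
    threshold_segment,
    to_gray,
    ThresholdSpec,
)

__all__ = [
    "MethodVariant",
    "VARIANTS",
    "JointMeasurement",
    "MeasurementResult",
    "vector_angle",
    "measure_joints",
    "run_pipeline",
]

_FLEXION_LABELS = ("MCP", "PIP", "DIP")


@dataclass(frozen=True)
class MethodVariant:
    """One of the four segmentation x line-extraction method combinations."""

    name: str
    segmentation: Literal["hsv", "threshold"]
    line: Literal["hough", "lsq"]


#: The four variants, keyed by their conventional acronyms:
#: HSV/threshold segmentation crossed with Hough inner-outer / least-squares
#: line extraction.  ``ts-homldm`` is the selected default.
VARIANTS: dict[str, MethodVariant] = {
    "hsv-hoislm": MethodVariant("hsv-hoislm", "hsv", "hough"),
    "hsv-lsflkadm": MethodVariant("hsv-lsflkadm", "hsv", "lsq"),
    "ts-homldm": MethodVariant("ts-homldm", "threshold", "hough"),
    "ts-lsflm": MethodVariant("ts-lsflm", "threshold", "lsq"),
}

DEFAULT_VARIANT = "ts-homldm"


@dataclass(frozen=True)
class JointMeasurement:
    """One joint: inner/outer/averaged angle (deg) and its image center."""

    label: str
    theta_inner: float
    theta_outer: float
    theta: float
    center_px: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "theta_inner": self.theta_inner,
            "theta_outer": self.theta_outer,
            "theta": self.theta,
            "center_px": None if self.center_px is None
            else [float(v) for v in self.center_px],
        }


@dataclass(frozen=True)
class MeasurementResult:
    """Full pipeline output: per-joint angles plus optional mm lengths."""

    variant: str
    mode: str
    joints: tuple[JointMeasurement, ...]
    lengths_mm: dict | None = None  # {"proximal": .., "middle": ..}
    diagnostics: dict = field(default_factory=dict)

    @property
    def angles(self) -> np.ndarray:
        return np.array([j.theta for j in self.joints])

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "variant": self.variant,
            "mode": self.mode,
            "joints": [j.to_dict() for j in self.joints],
            "lengths_mm": self.lengths_mm,
            "diagnostics": self.diagnostics,
        }


def vector_angle(a, b) -> float:
    """Angle between two 2-D vectors in degrees, in [0, 180].

    arccos of the normalized dot product; symmetric and invariant under
    positive scaling of either argument.  Raises on zero vectors.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-15 or nb < 1e-15:
        raise MeasurementError("vector_angle undefined for zero vectors")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _joint_center(ax_a: MarkerAxis, ax_b: MarkerAxis, theta: float,
                  cfg: PipelineConfig) -> np.ndarray:
    """Intersection of consecutive centerlines; midpoint of the facing
    endpoints when the joint is nearly straight (lines near-parallel)."""
    if theta > cfg.measure.parallel_fallback_deg:
        return 0.5 * (ax_a.tail + ax_b.head)
    center = ax_a.centerline.intersection(ax_b.centerline)
    d = min(np.linalg.norm(center - 0.5 * (ax_a.head + ax_a.tail)),
            np.linalg.norm(center - 0.5 * (ax_b.head + ax_b.tail)))
    if d > cfg.measure.max_joint_distance_px:
        raise MeasurementError(
            f"joint center {np.round(center, 1)} lies {d:.0f} px from both "
            f"markers (> {cfg.measure.max_joint_distance_px}); "
            f"line intersection unreliable"
        )
    return center


def measure_joints(
    axes: Sequence[MarkerAxis],
    h: PlanarHomography | None = None,
    mode: Literal["flexion", "abduction"] = "flexion",
    cfg: PipelineConfig | None = None,
) -> MeasurementResult:
    """Convert 4 ordered marker axes into 3 joint measurements.

    Flexion: vectors point away from the shared joint (marker i reversed,
    marker i+1 kept), labels MCP/PIP/DIP proximal to distal; phalanx lengths
    (proximal, middle) are mm distances between consecutive joint centers
    when ``h`` is given.  Abduction: positional pairing of outward
    directions, no reversal, no lengths.
    """
    cfg = cfg or PipelineConfig()
    if len(axes) != 4:
        raise MeasurementError(f"need 4 marker axes, got {len(axes)}")
    joints: list[JointMeasurement] = []
    centers: list[np.ndarray] = []
    for i in range(3):
        a, b = axes[i], axes[i + 1]
        if mode == "flexion":
            th_in = vector_angle(-a.inner_dir, b.inner_dir)
            th_out = vector_angle(-a.outer_dir, b.outer_dir)
        else:
            th_in = vector_angle(a.inner_dir, b.inner_dir)
            th_out = vector_angle(a.outer_dir, b.outer_dir)
        theta = (th_out + th_in) / 2.0
        label = _FLEXION_LABELS[i] if mode == "flexion" else f"pair-{i}"
        center = None
        if mode == "flexion":
            center = _joint_center(a, b, theta, cfg)
            centers.append(center)
        joints.append(JointMeasurement(
            label=label, theta_inner=th_in, theta_outer=th_out,
            theta=theta, center_px=center,
        ))
    lengths = None
    if h is not None and mode == "flexion":
        lengths = {
            "proximal": world_distance(h, centers[0], centers[1]),
            "middle": world_distance(h, centers[1], centers[2]),
        }
    return MeasurementResult(
        variant="", mode=mode, joints=tuple(joints), lengths_mm=lengths,
    )


def run_pipeline(
    img: np.ndarray,
    variant: str | MethodVariant = DEFAULT_VARIANT,
    h: PlanarHomography | None = None,
    mode: Literal["flexion", "abduction"] = "flexion",
    cfg: PipelineConfig | None = None,
    keep_intermediates: bool = False,
    proximal_hint=None,
) -> MeasurementResult:
    """Run the full measurement pipeline on one RGB image.

    Stages: segmentation (per the variant) -> contour filtering -> edge/line
    extraction -> joint measurement.  Stage failures are re-raised as
    :class:`PipelineError` with the stage name attached.  Lengths are
    reported only when a homography is supplied.  ``proximal_hint`` (a
    pixel point on the proximal side, known from the rig layout) resolves
    the intrinsic end-labeling ambiguity of four identical markers; without
    it the image-left end of the chain is taken as proximal.
    """
    cfg = (cfg or PipelineConfig()).validate()
    if isinstance(variant, str):
        try:
            variant = VARIANTS[variant]
        except KeyError:
            raise PipelineError(
                "setup", f"unknown variant {variant!r}; expected one of "
                f"{sorted(VARIANTS)}") from None

    diagnostics: dict = {"variant": variant.name}
    # -- segmentation ------------------------------------------------------
    try:
        if variant.segmentation == "hsv":
            hsv = rgb_to_hsv(img)
            mask = hsv_in_range(hsv, lo=(cfg.hsv.h[0], cfg.hsv.s[0],
                                         cfg.hsv.v[0]),
                                hi=(cfg.hsv.h[1], cfg.hsv.s[1],
                                    cfg.hsv.v[1]))
        else:
            gray = to_gray(img)
            if cfg.threshold.mode == "automatic":
                spec = auto_threshold(gray)
            else:
                spec = ThresholdSpec(t=cfg.threshold.t, mode="fixed")
            diagnostics["threshold_t"] = spec.t
            mask = threshold_segment(gray, spec)
        contours = find_contours(mask, min_pixels=cfg.contour.min_pixels)
        markers = filter_marker_contours(contours, expected=4,
                                         tol=cfg.contour.area_tol,
                                         proximal_hint=proximal_hint)
        diagnostics["marker_areas_px2"] = [round(c.area, 1) for c in markers]
    except SegmentationError as e:
        raise PipelineError("segmentation", str(e)) from e

    # -- line extraction ---------------------------------------------------
    try:
        edges = None
        if variant.line == "hough":
            # Canny on the segmentation mask: marker boundaries are the only
            # gradients, identically for both segmentation routes.
            edges = canny(mask.values.astype(float), cfg.canny.sigma,
                          cfg.canny.low, cfg.canny.high)
        axes = extract_marker_axes(
            markers, method=variant.line, edges=edges, cfg=cfg,
            layout="fan" if mode == "abduction" else "chain")
    except LineExtractionError as e:
        raise PipelineError("line_extraction", str(e)) from e

    # -- measurement -------------------------------------------------------
    try:
        result = measure_joints(axes, h=h, mode=mode, cfg=cfg)
    except (MeasurementError, LineExtractionError) as e:
        raise PipelineError("measurement", str(e)) from e

    if keep_intermediates:
        diagnostics["mask"] = mask
        diagnostics["edges"] = edges
        diagnostics["axes"] = axes
    return MeasurementResult(
        variant=variant.name, mode=mode, joints=result.joints,
        lengths_mm=result.lengths_mm, diagnostics=diagnostics,
    )
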