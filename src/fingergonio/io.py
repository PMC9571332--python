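"""Result and image file plumbing: schema-versioned JSON, flat CSV, PNG."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import FingergonioError
from .joint_measurement import JointMeasurement, MeasurementResult
from .segmentation import BinaryMask

__all__ = [
    "write_results", "read_results", "read_image", "write_image",
    "write_mask", "contours_to_json",
]


def write_results(result: MeasurementResult, fmt: str,
                  path: str | Path) -> Path:
    """Write a measurement result as JSON (full, round-trippable) or CSV
    (one row per joint: label, theta_inner, theta_outer, theta,
    proximal_mm, middle_mm)."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(result.to_dict(), indent=2))
    elif fmt == "csv":
        lengths = result.lengths_mm or {}
        rows = [{
            "variant": result.variant, "mode": result.mode,
            "label": j.label, "theta_inner": j.theta_inner,
            "theta_outer": j.theta_outer, "theta": j.theta,
            "proximal_mm": lengths.get("proximal"),
            "middle_mm": lengths.get("middle"),
        } for j in result.joints]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise FingergonioError(f"unsupported result format {fmt!r} "
                               "(expected 'json' or 'csv')")
    return path


def read_results(path: str | Path) -> MeasurementResult:
    """Read a JSON measurement result back; inverse of JSON write."""
    d = json.loads(Path(path).read_text())
    joints = tuple(
        JointMeasurement(
            label=j["label"], theta_inner=j["theta_inner"],
            theta_outer=j["theta_outer"], theta=j["theta"],
            center_px=None if j.get("center_px") is None
            else np.asarray(j["center_px"], dtype=float),
        )
        for j in d["joints"]
    )
    return MeasurementResult(
        variant=d["variant"], mode=d["mode"], joints=joints,
        lengths_mm=d.get("lengths_mm"), diagnostics=d.get("diagnostics", {}),
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF/JPEG); alpha is dropped."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return np.ascontiguousarray(img[..., :3]).astype(np.uint8)


def write_image(img: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    write_image(mask.values.astype(np.uint8), path)


def contours_to_json(contours, path: str | Path) -> None:
    payload = [{
        "points": c.points.tolist(),
        "area": c.area,
        "pixel_count": c.pixel_count,
        "centroid": c.centroid.tolist(),
    } for c in contours]
    Path(path).write_text(json.dumps(payload))
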