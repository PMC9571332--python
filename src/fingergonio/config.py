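"""Pipeline configuration: validated defaults, YAML/JSON loading.

Only the HSV gates are fixed by the measurement protocol (H 100–130,
S 150–255, V 130–255 in the degrees/2, 0–255 convention); every other
parameter is an implementation default, documented here and overridable
from a config file.  Unknown keys and out-of-range values are rejected
with the offending key named.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig", "load_config", "dump_config"]


def _check(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {msg}")


@dataclass(frozen=True)
class HsvGates:
    h: tuple[float, float] = (100, 130)
    s: tuple[float, float] = (150, 255)
    v: tuple[float, float] = (130, 255)

    def validate(self, prefix: str = "hsv") -> None:
        for name, (lo, hi), top in (("h", self.h, 180), ("s", self.s, 255),
                                    ("v", self.v, 255)):
            _check(0 <= lo <= hi <= top, f"{prefix}.{name}",
                   f"range [{lo}, {hi}] invalid (must be within [0, {top}])")


@dataclass(frozen=True)
class ThresholdCfg:
    mode: str = "automatic"  # "automatic" | "fixed"
    t: int | None = None  # required for fixed mode
    target: int = 0
    background: int = 255

    def validate(self, prefix: str = "threshold") -> None:
        _check(self.mode in ("automatic", "fixed"), f"{prefix}.mode",
               f"unknown mode {self.mode!r}")
        if self.mode == "fixed":
            _check(self.t is not None and 0 <= self.t <= 255, f"{prefix}.t",
                   "fixed mode needs t in [0, 255]")
        _check(self.target != self.background, f"{prefix}.target",
               "target and background labels must differ")


@dataclass(frozen=True)
class CannyCfg:
    sigma: float = 1.4
    low: float = 50.0
    high: float = 150.0

    def validate(self, prefix: str = "canny") -> None:
        _check(self.sigma > 0, f"{prefix}.sigma", "must be > 0")
        _check(self.low > 0, f"{prefix}.low", "must be > 0")
        _check(self.high >= self.low, f"{prefix}.high", "must be >= low")


@dataclass(frozen=True)
class HoughCfg:
    rho_res_px: float = 1.0
    theta_res_deg: float = 1.0
    vote_threshold: int | None = None  # None: 0.5 x marker long-edge length
    bbox_pad_px: int = 6
    min_edge_offset_px: float = 1.5
    refine_lines: bool = True
    refine_corridor_px: float = 2.0

    def validate(self, prefix: str = "hough") -> None:
        _check(self.rho_res_px > 0, f"{prefix}.rho_res_px", "must be > 0")
        _check(self.theta_res_deg > 0, f"{prefix}.theta_res_deg",
               "must be > 0")
        if self.vote_threshold is not None:
            _check(self.vote_threshold > 0, f"{prefix}.vote_threshold",
                   "must be > 0 (or null for automatic)")
        _check(self.bbox_pad_px >= 0, f"{prefix}.bbox_pad_px", "must be >= 0")
        _check(self.refine_corridor_px > 0, f"{prefix}.refine_corridor_px",
               "must be > 0")


@dataclass(frozen=True)
class ContourCfg:
    area_tol: float = 0.25  # relative (max-min)/mean spread allowed
    min_pixels: int = 20

    def validate(self, prefix: str = "contour") -> None:
        _check(self.area_tol > 0, f"{prefix}.area_tol", "must be > 0")
        _check(self.min_pixels >= 1, f"{prefix}.min_pixels", "must be >= 1")


@dataclass(frozen=True)
class MeasureCfg:
    near_parallel_bound_deg: float = 10.0
    parallel_fallback_deg: float = 175.0  # use endpoint midpoint beyond this
    max_joint_distance_px: float = 400.0
    decimals: int = 2

    def validate(self, prefix: str = "measure") -> None:
        _check(0 < self.near_parallel_bound_deg < 90,
               f"{prefix}.near_parallel_bound_deg", "must be in (0, 90)")
        _check(90 < self.parallel_fallback_deg <= 180,
               f"{prefix}.parallel_fallback_deg", "must be in (90, 180]")
        _check(self.max_joint_distance_px > 0,
               f"{prefix}.max_joint_distance_px", "must be > 0")
        _check(self.decimals >= 0, f"{prefix}.decimals", "must be >= 0")


@dataclass(frozen=True)
class PipelineConfig:
    hsv: HsvGates = field(default_factory=HsvGates)
    threshold: ThresholdCfg = field(default_factory=ThresholdCfg)
    canny: CannyCfg = field(default_factory=CannyCfg)
    hough: HoughCfg = field(default_factory=HoughCfg)
    contour: ContourCfg = field(default_factory=ContourCfg)
    measure: MeasureCfg = field(default_factory=MeasureCfg)
    verbosity: int = 1

    def validate(self) -> "PipelineConfig":
        self.hsv.validate()
        self.threshold.validate()
        self.canny.validate()
        self.hough.validate()
        self.contour.validate()
        self.measure.validate()
        _check(self.verbosity >= 0, "verbosity", "must be >= 0")
        return self

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: conv(getattr(obj, f.name))
                        for f in fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _build(cls, data, prefix="")


def _build(dc_type, data: dict, prefix: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{prefix or 'config'}: expected a mapping")
    known = {f.name: f for f in fields(dc_type)}
    unknown = set(data) - set(known)
    if unknown:
        where = f"{prefix}." if prefix else ""
        raise ConfigError(f"unknown key(s): "
                          f"{', '.join(where + k for k in sorted(unknown))}")
    kwargs = {}
    for name, f in known.items():
        if name not in data:
            continue
        val = data[name]
        sub = f.default_factory() if f.default_factory is not dataclasses.MISSING else None  # noqa: E501
        if dataclasses.is_dataclass(sub):
            kwargs[name] = _build(type(sub), val,
                                  f"{prefix}.{name}" if prefix else name)
        elif isinstance(val, list):
            kwargs[name] = tuple(val)
        else:
            kwargs[name] = val
    return dc_type(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline config; None or an empty
    file gives the full defaults."""
    if path is None:
        return PipelineConfig().validate()
    text = Path(path).read_text()
    if not text.strip():
        return PipelineConfig().validate()
    data = yaml.safe_load(text)  # YAML is a JSON superset
    if data is None:
        return PipelineConfig().validate()
    return PipelineConfig.from_dict(data).validate()


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a config as YAML (or JSON when the path ends in .json)."""
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(cfg.to_dict(), indent=2))
    else:
        p.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
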