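"""Exception hierarchy for the measurement pipeline.

Every stage raises a specific subclass; :class:`PipelineError` wraps a stage
failure with the stage name attached so CLI users can see where a run died.
"""

from __future__ import annotations


class FingergonioError(Exception):
    """Base class for all package errors."""


class CalibrationError(FingergonioError):
    """Degenerate correspondences or an unusable homography."""


class SegmentationError(FingergonioError):
    """Marker segmentation or contour filtering failed."""


class LineExtractionError(FingergonioError):
    """Edge/line detection could not produce the required marker lines."""


class MeasurementError(FingergonioError):
    """Joint-angle or length computation failed."""


class ConfigError(FingergonioError):
    """Invalid pipeline configuration."""


class PipelineError(FingergonioError):
    """A staged pipeline failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
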