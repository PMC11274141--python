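"""Exception hierarchy shared across the toolkit.

Every pipeline failure names the stage that produced it so a CLI run can
report *where* a bitewing image defeated the algorithm, not just that it did.
"""

from __future__ import annotations


class BitewingError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(BitewingError, ValueError):
    """An operator parameter violates its contract (even kernel, bad sigma...)."""


class GeometryError(BitewingError, ValueError):
    """Requested phantom geometry cannot fit inside the image."""


class FormatError(BitewingError, ValueError):
    """A file could not be read or written in the expected format."""


class SegmentationError(BitewingError, RuntimeError):
    """The segmentation pipeline failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class UndefinedMetricError(BitewingError, ZeroDivisionError):
    """A metric's denominator is zero; the value is undefined, not 0."""
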