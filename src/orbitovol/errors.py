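"""Exception hierarchy.

Exit-code mapping used by the CLI: validation errors -> 2,
segmentation errors -> 3, statistics errors -> 4.
"""


class OrbitovolError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(OrbitovolError):
    """Invalid inputs, malformed files, violated invariants."""

    exit_code = 2


class GeometryError(ValidationError):
    """Impossible phantom or landmark geometry (e.g. overlapping cavities)."""


class SegmentationError(OrbitovolError):
    """Contour / region extraction failures."""

    exit_code = 3


class NoEnclosingBoneError(SegmentationError):
    """No bony ring surrounds the seed point in a slice."""


class UnclosableContourError(SegmentationError):
    """A wall interruption is wider than the configured chord limit."""

    def __init__(self, gap_mm: float, max_gap_mm: float):
        self.gap_mm = gap_mm
        self.max_gap_mm = max_gap_mm
        super().__init__(
            f"unclosable contour: gap of {gap_mm:.2f} mm exceeds "
            f"max_gap_mm={max_gap_mm:.2f}"
        )


class PartialMeasurementError(SegmentationError):
    """A slice failed mid-stack; carries the slices completed so far."""

    def __init__(self, slice_index: int, cause: Exception, completed):
        self.slice_index = slice_index
        self.cause = cause
        self.completed = list(completed)
        super().__init__(f"slice {slice_index} failed: {cause}")


class StatisticsError(OrbitovolError):
    exit_code = 4


class DegenerateVarianceError(StatisticsError):
    """Paired differences have zero variance; the t statistic is undefined."""
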