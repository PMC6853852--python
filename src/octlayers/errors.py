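"""Exception hierarchy for octlayers."""


class OctLayersError(Exception):
    """Base class for all octlayers errors."""


class DegenerateImageError(OctLayersError):
    """Raised when an operation needs a non-constant image or weight set."""


class ParameterError(OctLayersError, ValueError):
    """Raised for out-of-range configuration parameters."""


class FormatError(OctLayersError):
    """Raised for unreadable or unsupported image files."""


class SchemaError(OctLayersError):
    """Raised when a boundary CSV does not carry the expected columns."""


class RegionEmptyError(OctLayersError):
    """Raised when a search region leaves no admissible rows in some column."""


class NoPathError(OctLayersError):
    """Raised when no left-to-right path exists inside the search region."""


class BoundaryOrderError(OctLayersError):
    """Raised when reference boundaries used to limit a region cross."""


class UndefinedMetricError(OctLayersError):
    """Raised when a metric is requested on an empty or degenerate input."""


class SegmentationStageError(OctLayersError):
    """A sequential segmentation stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")
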