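"""Exception hierarchy for feedkin.

Validation problems (bad files, bad configs) raise subclasses of
:class:`FeedkinError` so callers — and the CLI — can distinguish user input
errors from genuine pipeline failures.
"""


class FeedkinError(Exception):
    """Base class for all feedkin-specific errors."""


class SchemaError(FeedkinError):
    """A required column or field is missing or misnamed."""


class SamplingError(FeedkinError):
    """The time base is non-uniform or inconsistent with the declared rate."""


class ValidationError(FeedkinError):
    """Data fails a structural invariant (NaN runs, empty series, ...)."""


class SegmentationError(FeedkinError):
    """An expected phase-boundary event could not be found."""

    def __init__(self, boundary: str, message: str | None = None):
        self.boundary = boundary
        super().__init__(message or f"segmentation failed at boundary: {boundary}")


class DegeneratePathError(FeedkinError):
    """Start and end of a path window coincide; relative distance undefined."""


class UndefinedTestError(FeedkinError):
    """All paired differences are zero; the signed-rank test is undefined."""


class ParticipantExclusionError(FeedkinError):
    """No successful eating cycle exists for this participant/condition."""


class ConfigError(FeedkinError):
    """A pipeline configuration value is missing or invalid."""
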