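"""Structured exceptions used across the pipeline.

All errors derive from :class:`SpherotrackError` so callers can catch the
package's failures in one clause; per-well processing in the pipeline
converts them into recorded warnings rather than aborting a run.
"""


class SpherotrackError(Exception):
    """Base class for all spherotrack errors."""


class InvalidArgumentError(SpherotrackError, ValueError):
    """An argument violates a documented precondition."""


class RenderOverflowError(SpherotrackError):
    """The requested spheroid does not fit in the configured field of view."""


class NoSpheroidFoundError(SpherotrackError):
    """Segmentation produced no acceptable foreground component."""


class BoundaryClippedError(SpherotrackError):
    """The spheroid touches the image border; the contour is not closed."""


class SchemaError(SpherotrackError, ValueError):
    """A tabular input fails validation (missing column, duplicate well, ...)."""


class DegenerateControlError(SpherotrackError):
    """Control wells carry no positive signal; normalization is undefined."""


class InsufficientDataError(SpherotrackError):
    """Too few data points for the requested fit."""
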