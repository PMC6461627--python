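"""Exception hierarchy.

Every error raised by the library derives from :class:`CapRhythmError`, so
callers (and the CLI) can distinguish data problems from programming errors.
"""


class CapRhythmError(Exception):
    """Base class for all library errors."""


class FormatError(CapRhythmError):
    """Input file is malformed (missing column, unparseable cell)."""


class SpacingError(CapRhythmError):
    """Timestamps are not uniformly spaced within tolerance."""


class DataError(CapRhythmError):
    """A value is missing or non-finite."""


class DomainError(CapRhythmError, ValueError):
    """An argument is outside its mathematical domain."""


class ParameterError(CapRhythmError, ValueError):
    """An analysis parameter is invalid (bad scale grid, lag too large...)."""


class DegenerateSeriesError(CapRhythmError):
    """The series carries no usable variance."""


class InsufficientDataError(CapRhythmError):
    """Too few observations for the requested operation."""


class AlignmentError(CapRhythmError):
    """Two series do not share a common time axis."""


class InsufficientOverlapError(CapRhythmError):
    """Fewer than the minimum overlapping points at some offset."""


class InsufficientExtremaError(CapRhythmError):
    """Fewer than two peaks or two valleys detectable."""


class StateError(CapRhythmError):
    """Operation called on a result in the wrong state."""
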