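"""Exception hierarchy for the runcoord pipeline."""


class RuncoordError(Exception):
    """Base class for all runcoord errors."""


class DescriptorMismatchError(RuncoordError):
    """CSV content does not match the session descriptor."""


class SignalParseError(RuncoordError):
    """Non-numeric or malformed cell in a recording CSV."""


class MetadataError(RuncoordError):
    """Invalid or duplicate channel metadata."""


class AlignmentError(RuncoordError):
    """Channels share no common time interval."""


class ParameterError(RuncoordError):
    """An operation parameter is out of its valid range."""


class PeriodicityError(RuncoordError):
    """No periodic structure found in the search range."""


class SegmentationError(RuncoordError):
    """Gait cycle segmentation failed (too few peaks/events)."""


class InsufficientDataError(RuncoordError):
    """Fewer cycles/values available than required."""


class EnvelopeError(RuncoordError):
    """Energy envelope cannot be constructed (too-sparse signal)."""


class SymmetryUndefinedError(RuncoordError):
    """Correlation undefined (zero-variance envelope)."""


class ConfigurationError(RuncoordError):
    """Analysis configuration inconsistent with the recording."""


class ConsistencyError(RuncoordError):
    """Reports being merged do not refer to the same recording."""
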