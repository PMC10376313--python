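"""Exception hierarchy shared by every stressbox module."""


class StressboxError(Exception):
    """Base class for all stressbox errors."""


class ParseError(StressboxError):
    """A text file contained rows that could not be parsed as numbers."""


class FormatError(StressboxError):
    """A file parsed but violated a structural expectation (e.g. time step)."""


class ParameterError(StressboxError, ValueError):
    """An argument is outside its valid domain (e.g. cutoff above Nyquist)."""


class ValidationError(StressboxError, ValueError):
    """A data object violates one of its invariants."""


class SchemaError(StressboxError):
    """Feature names / arity do not match what a fitted model expects."""


class InsufficientDataError(StressboxError):
    """Too few samples, beats or intervals for the requested computation."""


class DetectionError(StressboxError):
    """No usable events (e.g. R peaks) could be detected in a signal."""


class EstimationError(StressboxError):
    """A spectral or rate estimate could not be formed with confidence."""


class UnlabeledSampleError(StressboxError):
    """Every labeling rule abstained; the sample cannot be labeled."""
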