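"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: parameter/dimension errors -> 2,
I/O and parse errors -> 3, layout incompatibilities -> 4.
"""


class DrowsyHogError(Exception):
    """Base class for all package errors."""


class ParameterError(DrowsyHogError, ValueError):
    """An argument violates a documented precondition."""


class DimensionError(ParameterError):
    """Array or image dimensions are invalid for the operation."""


class ExtractionError(DrowsyHogError):
    """A region of interest could not be extracted (e.g. empty intersection)."""


class AnnotationParseError(DrowsyHogError):
    """A ROI annotation file is malformed; message names the offending line."""


class BackendError(DrowsyHogError):
    """A face-detector backend failed internally."""


class FitError(DrowsyHogError):
    """Training data cannot support a model fit (e.g. a class with too few samples)."""


class NotFittedError(DrowsyHogError):
    """Prediction requested from a model that has not been fitted."""


class IncompatibilityError(DrowsyHogError):
    """Model and descriptor layouts disagree; message names both layouts."""
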