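"""Exception hierarchy for quantification failures.

Every anticipated failure mode maps to a distinct class so callers (and the
CLI) can distinguish bad parameters from degenerate data.
"""


class AxonContactError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AxonContactError, ValueError):
    """An argument is outside its documented domain."""


class GeometryError(AxonContactError):
    """A trace, point or ROI falls outside the image it refers to."""


class DegenerateInputError(AxonContactError):
    """Input is structurally valid but carries no usable signal
    (e.g. a constant image offered for automatic thresholding)."""


class UndefinedFractionError(AxonContactError):
    """A ratio's denominator is zero (e.g. an all-dark ribosome channel)."""


class NormalizationError(AxonContactError):
    """A batch lacks the control measurements needed for normalization."""


class AlignmentError(AxonContactError):
    """Curves offered for averaging do not share a common time grid."""


class RangeError(AxonContactError):
    """A requested time or position lies outside the sampled span."""


class ConfigError(AxonContactError):
    """A config/manifest references unknown presets, labels or files."""
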