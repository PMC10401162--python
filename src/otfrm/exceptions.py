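"""Exception types shared across the package.

All inherit from :class:`OTFRMError` so callers can catch package errors
with a single except clause; most also inherit ``ValueError`` since they
signal invalid inputs rather than internal failures.
"""


class OTFRMError(Exception):
    """Base class for all package errors."""


class ParseError(OTFRMError, ValueError):
    """A file did not conform to the expected on-disk format."""


class DegenerateInputError(OTFRMError, ValueError):
    """Input on which the requested quantity is mathematically undefined
    (e.g. a zero-norm vector under cosine distance)."""


class UndefinedStatisticError(OTFRMError, ValueError):
    """A statistic whose defining normalization is undefined for this
    input size (e.g. intra-task similarity with a single sample)."""


class IllConditionedRatioError(OTFRMError, ValueError):
    """A ratio whose denominator fell below the positivity guard."""

    def __init__(self, message: str, numerator: float, denominator: float):
        super().__init__(message)
        self.numerator = numerator
        self.denominator = denominator


class ConvergenceError(OTFRMError, RuntimeError):
    """Iterative solver failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class SizeError(OTFRMError, ValueError):
    """Problem instance exceeds a solver's size guard."""


class EncodingError(OTFRMError, ValueError):
    """Annotation spans cannot be encoded (overlap or out of bounds)."""


class DecodingError(OTFRMError, ValueError):
    """A tag sequence violates the BIOES grammar."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class GenerationError(OTFRMError, ValueError):
    """Synthetic-data generation infeasible at the requested parameters."""
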