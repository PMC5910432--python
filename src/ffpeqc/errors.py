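"""Exception hierarchy shared across the package."""


class FfpeqcError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FfpeqcError, ValueError):
    """A simulation or analysis parameter violates its documented constraints."""


class InvalidInputError(FfpeqcError, ValueError):
    """An input object (trace, matrix, table) violates its invariants."""


class UndefinedMetricError(FfpeqcError, ArithmeticError):
    """The requested metric is mathematically undefined for this input
    (e.g. DV200 of an all-zero trace, Pearson r of a constant sample)."""


class ParseError(FfpeqcError, ValueError):
    """A file could not be parsed; the message names the file and location."""


class ValidationError(FfpeqcError, ValueError):
    """Cross-file consistency check failed (e.g. sample sheet vs. matrix)."""
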