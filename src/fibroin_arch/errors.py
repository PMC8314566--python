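"""Exception hierarchy shared across the package."""


class FibroinArchError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FibroinArchError, ValueError):
    """A configuration or parameter value violates its invariant.

    The message always names the offending field.
    """


class InputError(FibroinArchError, ValueError):
    """Input data (sequence, table, ...) violates an operation precondition."""


class ParseError(FibroinArchError, ValueError):
    """A file could not be parsed; the message locates the problem."""


class UndefinedCorrelationError(FibroinArchError, ValueError):
    """Correlation requested on a constant (zero-variance) vector."""
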