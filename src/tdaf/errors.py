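"""Exception hierarchy shared across the package."""


class TdafError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TdafError):
    """A signal file contains a row that cannot be interpreted.

    Attributes
    ----------
    line_number : int
        1-based line number of the offending row.
    """

    def __init__(self, message: str, line_number: int | None = None):
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(TdafError):
    """An input file or sequence contains no usable values."""


class InsufficientLengthError(TdafError):
    """A sequence is too short for the requested operation."""


class ConfigurationError(TdafError):
    """A parameter value violates the method's constraints."""


class DegenerateInputError(TdafError):
    """Input has no variance (or zero mean) where the statistic requires it."""


class BandError(TdafError):
    """A frequency band does not intersect the available spectrum."""
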