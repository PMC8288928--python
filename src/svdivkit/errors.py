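"""Exception hierarchy shared across the toolkit."""


class SVDivKitError(Exception):
    """Base class for all svdivkit errors."""


class ValidationError(SVDivKitError, ValueError):
    """A domain object violates one of its invariants."""


class InputFormatError(SVDivKitError, ValueError):
    """A file or record could not be parsed.

    ``line`` carries the 1-based line number in the source file when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InsufficientDataError(SVDivKitError, ValueError):
    """Not enough observations to compute the requested statistic."""


class UndefinedStatisticError(SVDivKitError, ArithmeticError):
    """The statistic is undefined for this input (e.g. all values missing)."""
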