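"""Exception hierarchy shared across the package."""


class RegpathError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RegpathError, ValueError):
    """A malformed row in an input file.

    Carries the 1-based line number of the offending row.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(RegpathError, ValueError):
    """Structurally valid input that violates a domain invariant."""


class ContractError(RegpathError, ValueError):
    """An operation called with arguments that break its contract."""
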