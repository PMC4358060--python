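"""Exception hierarchy shared across the package."""


class VectionSimError(ValueError):
    """Base class for all package-specific errors."""


class ConfigurationError(VectionSimError):
    """A configuration object violates one of its invariants."""


class AliasingError(ConfigurationError):
    """Requested sample rate cannot represent the requested oscillation."""


class DomainError(VectionSimError):
    """An argument lies outside the mathematical domain of an operation."""


class DesignError(VectionSimError):
    """A factorial design table is incomplete or malformed."""


class DegenerateDataError(VectionSimError):
    """Data carry no variance where a test statistic requires some."""


class AnalysisError(VectionSimError):
    """An analysis cannot proceed (e.g. too few detected turning points)."""


class ParseError(VectionSimError):
    """A text input file is malformed.

    Attributes
    ----------
    line : int or None
        1-based line number at which parsing failed, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
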