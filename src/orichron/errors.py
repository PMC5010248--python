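"""Exception hierarchy shared by all orichron modules."""


class OrichronError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(OrichronError, ValueError):
    """A map position lies outside the circular coordinate system."""


class ParameterError(OrichronError, ValueError):
    """A cell-cycle or model parameter violates its constraints."""


class ConfigurationError(OrichronError, ValueError):
    """A required piece of configuration (baseline, terminus, ...) is missing."""


class ValidationError(OrichronError, ValueError):
    """An input table failed semantic validation (e.g. duplicate locus names)."""


class ParseError(OrichronError, ValueError):
    """An input file could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyInputError(OrichronError, ValueError):
    """An operation that needs at least one record received none."""


class UndefinedIndexError(OrichronError, ValueError):
    """The asynchrony index is undefined (no cells with >= 2 origins)."""


class StepSizeError(OrichronError, ValueError):
    """The integration step is too coarse for the requested dynamics."""


class CalibrationError(OrichronError, RuntimeError):
    """Parameter calibration failed to satisfy its targets within bounds."""
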