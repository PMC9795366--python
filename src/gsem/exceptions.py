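"""Typed errors raised across the package."""


class GsemError(Exception):
    """Base class for all package errors."""


class ValidationError(GsemError):
    """An input violates a documented invariant (shape, sign, range...)."""


class IdentifierError(GsemError):
    """An entity identifier is unknown or duplicated."""


class ConfigurationError(GsemError):
    """Hyperparameters or configuration are inconsistent with the inputs."""


class NumericalError(GsemError):
    """A computation produced non-finite values."""


class DegenerateInputError(GsemError):
    """The input is formally valid but makes the requested quantity undefined."""


class UndefinedMetricError(GsemError):
    """A ranking metric was requested on single-class labels."""


class ParseError(GsemError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
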