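"""Exception hierarchy shared across the package."""


class SocnetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SocnetError):
    """An input table is missing a required column or has a bad layout."""


class RecordError(SocnetError):
    """A single input row is malformed (bad date, unknown category, ...)."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DomainError(SocnetError):
    """A numeric argument is outside the domain of an operation."""


class ConfigError(SocnetError):
    """An analysis configuration value is invalid."""


class ConsistencyError(SocnetError):
    """Two inputs that must agree (e.g. presence vs. co-occurrence) do not."""


class DegenerateInputError(SocnetError):
    """The input is too small or too uniform for the requested analysis."""


class NotApplicableError(SocnetError):
    """The operation does not apply to this input (caller must use another)."""
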