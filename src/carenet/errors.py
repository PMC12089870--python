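"""Exception hierarchy for the carenet pipeline."""


class CarenetError(Exception):
    """Base class for all carenet errors."""


class SchemaError(CarenetError):
    """An input file does not match its documented schema."""


class RecordValidationError(CarenetError):
    """One or more rows/records failed field-level validation."""

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message)
        self.rows = rows or []


class ConfigError(CarenetError):
    """A configuration value is missing or invalid."""


class ConsistencyError(CarenetError):
    """An internal cross-reference invariant was violated."""


class FittingError(CarenetError):
    """A statistical model could not be fitted on the given input."""
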