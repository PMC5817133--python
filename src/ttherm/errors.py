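"""Exception hierarchy shared across the pipeline stages."""


class TthermError(Exception):
    """Base class for all package errors."""


class SchemaError(TthermError):
    """A required column is missing or a file does not match its schema."""


class DuplicateTimestampError(TthermError):
    """Two records in a series share the same timestamp."""


class RowError(TthermError):
    """A single record failed validation; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class MalformedBurstError(RowError):
    """An accelerometer record does not hold exactly 36 finite readings."""


class EmptyInputError(TthermError):
    """An operation received an empty series or table."""


class ParameterError(TthermError):
    """An argument violates its stated constraint (e.g. max_gap <= 0)."""


class InsufficientDataError(TthermError):
    """Too few observations to compute the requested quantity."""


class SeparationError(TthermError):
    """Logistic fit diverged: the response is perfectly separated."""


class ComparabilityError(TthermError):
    """Model fits cannot be compared (different response rows)."""
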