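"""Exception hierarchy shared across the package."""

from __future__ import annotations


class MppycostError(Exception):
    """Base class for all package errors."""


class ValidationError(MppycostError, ValueError):
    """A parameter, record or table violated a documented invariant."""


class SchemaError(ValidationError):
    """An input table failed schema validation.

    Carries enough context (file, row, column) to locate the offending cell.
    Row numbers are 1-based data rows (the header is row 0).
    """

    def __init__(self, message: str, *, file: str, row: int | None = None,
                 column: str | None = None):
        self.file = file
        self.row = row
        self.column = column
        where = file
        if row is not None:
            where += f", row {row}"
        if column is not None:
            where += f", column '{column}'"
        super().__init__(f"{where}: {message}")


class ZeroFollowUpError(MppycostError):
    """A patient contributes no person-time to the requested period."""


class ZeroPersonTimeError(MppycostError):
    """A rate is undefined because total person-time is zero."""


class UndefinedChangeError(MppycostError):
    """Percent change from a zero baseline is undefined."""
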