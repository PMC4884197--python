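"""Shared exception types."""


class ValidationError(ValueError):
    """Raised when an input table or record violates a documented invariant.

    ``rows`` carries the offending row indices (0-based, data rows) when the
    error originates from a table.
    """

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = rows or []


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input
    (e.g. a CV of fewer than two values, or of an all-zero series)."""
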