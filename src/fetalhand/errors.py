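"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file or table does not have the expected structure (e.g. missing columns)."""


class ValidationError(ValueError):
    """Data are structurally readable but violate a domain invariant.

    Carries the offending row indices (0-based, counting data rows) when the
    failure originates from a tabular input.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = list(rows) if rows else []
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


class DegenerateDataError(ValueError):
    """A statistic is undefined on the given input (constant sample, single class...)."""
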