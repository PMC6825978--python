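"""Exception hierarchy shared across the package."""


class DasikitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DasikitError):
    """A value violates a data-model invariant."""


class SchemaError(DasikitError):
    """A table's columns do not match the documented column dictionary."""


class RowError(ValidationError):
    """A specific row of a cohort table failed validation.

    Carries the 0-based data-row index and the offending column so the
    message pinpoints the cell.
    """

    def __init__(self, row: int, column: str, message: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column '{column}': {message}")


class ComputationError(DasikitError):
    """An index or estimate could not be computed from otherwise-valid input."""


class ConvergenceError(DasikitError):
    """Model fitting failed to converge or the likelihood is degenerate."""
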