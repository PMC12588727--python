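"""Exception hierarchy for the outbreeding-response pipeline."""


class OutbreedingError(Exception):
    """Base class for all package errors."""


class ValidationError(OutbreedingError):
    """An input value violates a documented contract (vocabulary, range, shape)."""


class SchemaError(ValidationError):
    """A table file violates the tidy-cohort CSV schema.

    Carries ``row`` (1-based data row number) when the violation is row-local.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class InsufficientDataError(OutbreedingError):
    """A group is empty or too small after missing-value removal."""


class UndefinedInputError(OutbreedingError):
    """The statistic is undefined for this input (e.g. both group means zero)."""
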