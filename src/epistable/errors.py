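"""Exception hierarchy.

Errors are grouped by the stage that raises them so the command-line
front end can map them onto distinct exit codes.
"""


class EpistableError(Exception):
    """Base class for all package errors."""


class ModelFormatError(EpistableError):
    """The model file is malformed (CSV structure, row count, labels)."""


class ExpressionError(ModelFormatError):
    """A penetrance expression could not be parsed."""


class ModelDefinitionError(ModelFormatError):
    """The parsed model violates a structural requirement
    (e.g. it does not use exactly two variables)."""


class DomainError(EpistableError, ValueError):
    """An input value is outside its mathematical domain
    (MAF outside (0, 0.5], target outside (0, 1), ...)."""


class ValidationError(EpistableError):
    """Model admissibility validation (monotonicity / sortability) failed."""


class NoSolutionError(EpistableError):
    """No penetrance table with the requested characteristics exists.

    ``reasons`` carries per-candidate rejection diagnostics when roots
    were found but all of them were discarded.
    """

    def __init__(self, message: str, reasons: list[str] | None = None):
        super().__init__(message)
        self.reasons = reasons or []


class UnderdeterminedSystemError(NoSolutionError):
    """The equation system has fewer than two effective unknowns."""
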