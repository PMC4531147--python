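"""Exception hierarchy shared across the package."""

from __future__ import annotations


class GenotilerError(Exception):
    """Base class for all package errors."""


class ParseError(GenotilerError):
    """Syntax or validation error in DSL source, with position information."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        where = ""
        if line is not None:
            where = f" (line {line}" + (f", col {column}" if column is not None else "") + ")"
        super().__init__(message + where)


class ValidationError(GenotilerError):
    """A structurally invalid domain object (bad interval, duplicate label, ...)."""


class NotExpandedError(GenotilerError):
    """An operation that requires macro-free input received a macro rule."""


class NotGroundError(GenotilerError):
    """An operation that requires a variable-free program received variables."""


class DivisionError(GenotilerError):
    """A chronological division is malformed or incompatible with its trace."""


class SubstitutionConflictError(GenotilerError):
    """Two substitutions disagree on a shared variable, or injectivity fails."""


class UnobservableError(GenotilerError):
    """An assembly admits no bounded linear model: infeasible behaviour."""


class ResourceGuardExceeded(GenotilerError):
    """A bounded search exceeded its node budget."""


class LibraryFormatError(GenotilerError):
    """A library document fails schema or content validation."""


class InfeasibleConfigError(GenotilerError):
    """A benchmark configuration cannot produce the requested instance."""


class NoSolutionError(GenotilerError):
    """Compilation found no covering assembly.

    Carries a ``diagnosis`` string (e.g. the orphan goal rule with no locally
    associated component) and the :class:`~genotiler.evolution.CompileReport`
    accumulated up to the failure, when available.
    """

    def __init__(self, message: str, diagnosis: str | None = None, report=None):
        super().__init__(message)
        self.diagnosis = diagnosis
        self.report = report
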