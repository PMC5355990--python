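"""Exception hierarchy for the histotype package.

Every error raised by the package derives from :class:`HistotypeError` so
callers can catch package failures with a single except clause while tests
can still assert on the specific failure mode.
"""


class HistotypeError(Exception):
    """Base class for all histotype errors."""


class IdentifierError(HistotypeError):
    """Duplicate or otherwise invalid gene/sample identifiers."""


class MatrixParseError(HistotypeError):
    """A cell in an expression file could not be parsed as a number."""

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class DegenerateCohortError(HistotypeError):
    """A cohort has too few samples for per-cohort mean adjustment."""


class ConstantGeneError(HistotypeError):
    """A gene has zero variance and cannot be standardized."""


class ConfigurationError(HistotypeError):
    """Invalid parameter combination passed to an operation."""


class ClassCountError(HistotypeError):
    """An operation requiring both histologic classes saw only one."""


class GeneCoverageError(HistotypeError):
    """An expression matrix is missing genes required by a model."""

    def __init__(self, message: str, missing=()):
        super().__init__(message)
        self.missing = list(missing)


class StratificationError(HistotypeError):
    """Stratified cross-validation folds are infeasible."""


class SelectionError(HistotypeError):
    """No admissible shrinkage threshold could be selected."""


class CalibrationError(HistotypeError):
    """Cutoff calibration failed (e.g. all scores identical)."""


class UndefinedScoreError(HistotypeError):
    """A sample's signature sub-vector has zero variance."""


class MixtureError(HistotypeError):
    """Mixture fit is degenerate or its threshold is undefined."""


class JoinError(HistotypeError):
    """Sample identifiers do not match between two tables."""

    def __init__(self, message: str, orphans=()):
        super().__init__(message)
        self.orphans = list(orphans)


class GroupingError(HistotypeError):
    """A two-group statistical test received a single group."""


class ValidationError(HistotypeError):
    """Input values violate a basic contract (negative times, bad flags)."""


class DegenerateItemError(HistotypeError):
    """A row with zero norm cannot enter a correlation-based distance."""


class InsufficientRangeError(HistotypeError):
    """Too few cluster counts to assess consensus stability."""
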