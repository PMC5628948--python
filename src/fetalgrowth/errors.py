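"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`FetalGrowthError`, so callers can catch one type at pipeline level.
"""


class FetalGrowthError(Exception):
    """Base class for all package errors."""


class UnitError(FetalGrowthError):
    """Dimensionally incompatible or unknown unit conversion."""


class InvalidMeasurementError(FetalGrowthError):
    """A measurement is non-positive, non-finite, or out of ingest range."""


class IncompleteScanError(FetalGrowthError):
    """A formula requires a measurement the scan does not carry."""


class ConfigError(FetalGrowthError):
    """Missing or invalid configuration asset (coefficients, ranges, paths)."""


class DataError(FetalGrowthError):
    """Input data violates a precondition (size, span, monotonicity...)."""


class FitError(FetalGrowthError):
    """An iterative fit failed to converge; carries diagnostics in args."""


class SupportError(FetalGrowthError):
    """Requested quantile falls outside the Box-Cox support."""


class EligibilityError(DataError):
    """Scans do not satisfy the second-trimester window/separation rules."""


class ExtrapolationError(DataError):
    """Age outside the fitted reference grid; interpolation only."""


class TableLookupError(FetalGrowthError):
    """Age/probability pair outside the shipped reference table."""


class FormatError(FetalGrowthError):
    """Malformed CSV input; message carries line/column context."""


class DegenerateTableError(DataError):
    """Confusion table with an empty margin."""


class AmbiguityError(FetalGrowthError):
    """Integer confusion-table reconstruction has multiple solutions."""


class InconsistencyError(FetalGrowthError):
    """Integer confusion-table reconstruction has no solution."""


class CollinearityError(DataError):
    """Rank-deficient regression design."""
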