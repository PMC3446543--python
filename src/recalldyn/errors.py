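"""Exception hierarchy.

All package errors derive from :class:`RecallDynError` so callers can catch
one base class; subclasses distinguish schema problems in input files from
capacity/constraint failures in list construction and from statistically
undefined quantities (empty pooled cells).
"""


class RecallDynError(Exception):
    """Base class for all recalldyn errors."""


class SchemaError(RecallDynError):
    """An input table is malformed (missing column, invalid label, ...)."""


class ReferentialIntegrityError(SchemaError):
    """An events row references a stimulus list that was never defined."""


class DuplicateRowError(SchemaError):
    """A key that must be unique (word in norms, output position) repeats."""


class NormsLookupError(RecallDynError):
    """A stimulus word is absent from the norms table during a mean check."""


class CapacityError(RecallDynError):
    """Not enough eligible words / too large an enumeration request."""


class ConstraintFailureError(RecallDynError):
    """List construction could not satisfy its constraints within retries."""


class UndefinedMetricError(RecallDynError):
    """A pooled estimate has a zero denominator in the requested cell."""


class UndefinedStatisticError(RecallDynError):
    """A change or interaction statistic needs a cell that is undefined."""


class DegenerateDataError(RecallDynError):
    """Too many permutation replicates were undefined to trust the test."""


class ConfigurationError(RecallDynError):
    """A run configuration is inconsistent or incomplete."""
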