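"""Exception hierarchy for the heatdlnm pipeline."""


class HeatDLNMError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(HeatDLNMError):
    """A configuration object violates its invariants."""


class EmptyInputError(HeatDLNMError):
    """An operation received an empty series or table."""


class InsufficientHistoryError(HeatDLNMError):
    """The series is too short to cover the requested lag window."""


class InvalidKnotsError(HeatDLNMError):
    """Spline knots are duplicated or outside the boundary."""


class NoValidBreakpointError(HeatDLNMError):
    """Every candidate breakpoint left an empty or undersized segment."""


class AlignmentError(HeatDLNMError):
    """Series and design components do not cover the same days."""


class ConvergenceError(HeatDLNMError):
    """Iteratively reweighted least squares failed to converge."""


class DegenerateFitError(HeatDLNMError):
    """The response carries no information (zero variance)."""


class SchemaError(HeatDLNMError):
    """An input file is missing required columns or is malformed."""


class EmptyPeriodError(HeatDLNMError):
    """An aggregation period contains no days."""


class DuplicateKeyError(HeatDLNMError):
    """A scenario/period pair appears more than once in a table."""
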