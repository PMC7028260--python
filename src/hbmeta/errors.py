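"""Exception hierarchy shared across the package."""


class HbmetaError(Exception):
    """Base class for all package errors."""


class SchemaError(HbmetaError):
    """Input table is missing required columns or has malformed values."""


class ValidationError(HbmetaError):
    """A study record or category violates a structural invariant."""


class EmptyInputError(HbmetaError):
    """An operation received no usable rows/records/effects."""


class InsufficientDataError(HbmetaError):
    """Too few studies/categories for the requested analysis."""


class DoseAssignmentError(HbmetaError):
    """Dose cannot be assigned (all-open intervals, non-increasing result)."""


class NumericalError(HbmetaError):
    """Solver non-convergence or a singular system."""


class IdentifiabilityError(HbmetaError):
    """More coefficients than clusters, or a singular design."""
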