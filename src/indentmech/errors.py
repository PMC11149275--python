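"""Exception hierarchy for the indentation/BV-TV pipeline."""


class IndentmechError(Exception):
    """Base class for all package errors."""


class FormatError(IndentmechError):
    """A file does not have the expected columns or layout."""


class ValidationError(IndentmechError):
    """Input data violates a declared invariant (units, monotonic time, ...)."""


class SegmentationError(IndentmechError):
    """A curve does not match the ramp-hold-unload protocol signature."""


class ParameterError(IndentmechError):
    """An operation was called with invalid tuning parameters."""


class FitError(IndentmechError):
    """A regression window is degenerate or under-populated."""


class QCRejectedError(IndentmechError):
    """A downstream computation was requested for a QC-rejected fit."""


class DomainError(IndentmechError):
    """A physical parameter is outside the model's domain of validity."""


class NumericalError(IndentmechError):
    """A quadrature or linear solve failed to converge."""


class ExtrapolationError(IndentmechError):
    """A lookup-table query fell outside the tabulated hull."""
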