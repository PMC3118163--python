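"""Typed exceptions for the MLPA analysis pipeline.

The hierarchy separates data/contract problems (:class:`ValidationError`),
file-format problems (:class:`FormatError`), methods invoked on data that
cannot support them (:class:`MethodPreconditionError`) and numerical failures
of a fit (:class:`FitError`).  The CLI maps each class to a distinct exit
code.
"""


class MLPAError(Exception):
    """Base class for all package errors."""


class ValidationError(MLPAError, ValueError):
    """Input data violates a structural contract (shapes, labels, ranges)."""


class FormatError(ValidationError):
    """A tabular input file does not have the expected layout."""


class MethodPreconditionError(MLPAError):
    """A method was requested on data that cannot support it.

    Example: the nonlinear normalization or the mixed model on an
    experiment without technical replicates.
    """


class FitError(MLPAError):
    """A model fit is degenerate or failed to converge."""
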