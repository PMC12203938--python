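"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`SmstoichError` so callers can
distinguish pipeline failures from programming errors.
"""


class SmstoichError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SmstoichError, ValueError):
    """A parameter violates its documented constraint."""


class DimensionError(SmstoichError, ValueError):
    """Array shapes are inconsistent with each other or with the field."""


class CapacityError(SmstoichError):
    """The field cannot hold the requested number of spots at the given
    minimum separation."""


class RegistrationError(SmstoichError):
    """Channel registration failed; carries the number of matched beads."""

    def __init__(self, message: str, n_matched: int | None = None):
        super().__init__(message)
        self.n_matched = n_matched


class BorderExclusionError(SmstoichError):
    """A spot sits too close to the field border for aperture photometry."""


class EstimationError(SmstoichError):
    """An estimator received an empty or degenerate cohort."""


class TrainingError(SmstoichError):
    """The trajectory classifier cannot be trained on the given data."""


class FitFailureError(SmstoichError):
    """A nonlinear fit did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvalidInputError(SmstoichError, ValueError):
    """Statistical input is malformed (empty group, empty design cell...)."""
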