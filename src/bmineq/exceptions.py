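"""Exception types shared across the package."""


class BmineqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BmineqError):
    """A generator or analysis configuration is invalid; the message names the field."""


class DataValidationError(BmineqError):
    """An input table violates the survey schema; the message carries row context."""


class ConvergenceError(BmineqError):
    """An iterative fit failed to converge within its budget."""

    def __init__(self, message: str, last_deviation: float | None = None):
        super().__init__(message)
        self.last_deviation = last_deviation


class EstimationError(BmineqError):
    """An estimator was handed a degenerate input (constant outcome, empty cell...)."""
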