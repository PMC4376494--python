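"""Exception hierarchy shared by all pipeline stages."""


class VesselemError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VesselemError):
    """Raised when input data violates a precondition (bad pixels, shape mismatch...)."""


class ConfigurationError(VesselemError):
    """Raised when a configuration value is unusable for the given input."""


class NumericalError(VesselemError):
    """Raised when a computation fails numerically (e.g. singular covariance)."""
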