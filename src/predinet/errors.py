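"""Exception types shared across the package."""


class PredinetError(Exception):
    """Base class for package errors."""


class ParameterError(PredinetError, ValueError):
    """A parameter is outside its admissible domain."""


class DimensionError(PredinetError, ValueError):
    """Array shapes are inconsistent with the model configuration."""


class ConvergenceError(PredinetError, RuntimeError):
    """An iterative solve failed to reach the requested tolerance.

    Carries the residual history when available.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []


class IntegrationError(PredinetError, RuntimeError):
    """Numerical integration diverged or the step size is unstable."""


class RangeError(PredinetError, ValueError):
    """A requested value lies outside the attainable range of a formula."""


class NonIdentifiableError(PredinetError, ValueError):
    """The requested inversion does not constrain the parameter."""


class InsufficientDataError(PredinetError, ValueError):
    """Too few observations to compute the requested statistic."""


class ConfigError(PredinetError, ValueError):
    """A configuration file failed validation."""
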