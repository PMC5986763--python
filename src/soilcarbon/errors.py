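"""Package-wide exception types."""


class SoilCarbonError(Exception):
    """Base class for package errors."""


class InvalidParameterError(SoilCarbonError, ValueError):
    """A parameter violates its domain (e.g. non-positive Q10)."""


class InfeasibleParameterError(SoilCarbonError, ValueError):
    """A parameter vector yields no physical solution (negative transfer
    fraction, singular or negative steady state, negative quadratic root).

    The calibration layer converts this into a -inf log-likelihood rather
    than propagating the exception.
    """


class InvalidConfigurationError(SoilCarbonError, ValueError):
    """A configuration value is out of range."""
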