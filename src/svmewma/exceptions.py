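"""Exception hierarchy shared across the package."""


class SvmEwmaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SvmEwmaError, ValueError):
    """A parameter or configuration value is outside its admissible range."""


class DataError(SvmEwmaError, ValueError):
    """Input data violate a structural precondition (bad rows, empty streams...)."""


class FittingError(SvmEwmaError, RuntimeError):
    """A model fit failed (degenerate data or non-convergence)."""


class ConvergenceError(FittingError):
    """An iterative solver exhausted its iteration budget."""


class SeparabilityError(FittingError):
    """Hard-margin classification was requested on non-separable data."""


class StandardizationError(SvmEwmaError, RuntimeError):
    """Residual standardization is impossible (zero spread in the training pool)."""


class CalibrationError(SvmEwmaError, RuntimeError):
    """Control-limit calibration could not bracket or reach the target ARL."""
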