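"""Exception types shared across the package."""


class CloverQGError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CloverQGError, ValueError):
    """Invalid simulation or run configuration (negative variance, bad rate, ...)."""


class CapacityError(ConfigError):
    """Trial design cannot seat the requested number of families."""


class MissingControlError(CloverQGError, ValueError):
    """A required control treatment (negative or positive) has no records."""


class DegenerateControlError(CloverQGError, ValueError):
    """Positive- and negative-control means coincide; symbiotic potential undefined."""


class PairingError(CloverQGError, ValueError):
    """Two traits share no plots, so their covariance cannot be estimated."""


class SingularCovarianceError(CloverQGError, RuntimeError):
    """Total covariance matrix is not positive definite at the requested variances."""

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class ConvergenceError(CloverQGError, RuntimeError):
    """REML iterations failed to converge; carries the log-likelihood trajectory."""

    def __init__(self, message: str, trajectory=None):
        super().__init__(message)
        self.trajectory = list(trajectory) if trajectory is not None else []
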