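"""Exception types shared across the package."""


class PredcodingError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PredcodingError, ValueError):
    """A model parameter violates its constraint (e.g. non-positive variance)."""


class ConfigurationError(PredcodingError, ValueError):
    """A model/circuit configuration is inconsistent (wrong map kind, bad dims)."""


class DegeneratePosteriorError(PredcodingError, ArithmeticError):
    """All grid densities underflowed; the posterior cannot be normalized."""


class InstabilityError(PredcodingError, RuntimeError):
    """A simulated trajectory exceeded the overflow guard (Euler step too large
    or genuinely unstable dynamics)."""

    def __init__(self, message: str, step: int | None = None, dt: float | None = None):
        super().__init__(message)
        self.step = step
        self.dt = dt
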