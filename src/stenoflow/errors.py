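"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or out of the supported range."""


class ContractViolation(RuntimeError):
    """An internal precondition was violated (caller bug, not user input)."""


class ConvergenceError(RuntimeError):
    """The iterative solver failed to reach its residual target."""

    def __init__(self, message: str, worst_residual: float | None = None):
        super().__init__(message)
        self.worst_residual = worst_residual


class DivergenceError(RuntimeError):
    """The solution became non-finite (NaN/Inf detected)."""
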