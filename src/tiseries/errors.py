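"""Exception hierarchy shared across the package."""


class TiseriesError(Exception):
    """Base class for all package-specific errors."""


class DesignError(TiseriesError, ValueError):
    """An experiment design request is internally inconsistent."""


class InvalidPairError(DesignError):
    """A stimulus pair was constructed from invalid items."""


class CounterbalanceError(DesignError):
    """Side counterbalancing cannot be satisfied (odd presentation count)."""


class ConfigError(TiseriesError, ValueError):
    """An agent / RT / run configuration has out-of-range parameters."""


class ValidationError(TiseriesError, ValueError):
    """A data file or record failed validation."""


class GPNumericalError(TiseriesError, RuntimeError):
    """A linear-algebra step failed (singular system after jitter)."""


class ConvergenceError(TiseriesError, RuntimeError):
    """Newton iteration for the latent mode did not converge."""

    def __init__(self, message: str, iterations: int, last_change: float):
        super().__init__(message)
        self.iterations = iterations
        self.last_change = last_change


class OptimizationError(TiseriesError, RuntimeError):
    """All hyperparameter-optimization starts failed."""


class AnalysisError(TiseriesError, ValueError):
    """An analysis request cannot be computed from the given data."""
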