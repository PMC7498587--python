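"""Exception types shared across the package."""


class ChlTrendError(Exception):
    """Base class for chltrend-specific failures."""


class InvalidConfigurationError(ChlTrendError, ValueError):
    """A configuration or argument combination that cannot be satisfied."""


class DegenerateGeometryError(ChlTrendError):
    """Cell geometry that yields a non-positive-definite spatial covariance."""


class InsufficientDataError(ChlTrendError):
    """Not enough non-missing observations (or draws) to proceed."""


class EstimationFailureError(ChlTrendError):
    """An iterative estimator failed to converge.

    Carries the last iterate so callers can inspect how far it got.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class DivergenceError(ChlTrendError):
    """Non-finite values encountered during MCMC; carries the sweep index."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration
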