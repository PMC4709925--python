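"""Typed exceptions shared across the package."""


class AdcDesignError(Exception):
    """Base class for all package-specific errors."""


class DegenerateDesignError(AdcDesignError):
    """Raised when an operation needs an invertible information matrix but the
    acquisition design has fewer than two distinct b-values."""


class NonPositiveMeasurementError(AdcDesignError):
    """Raised when a log-linear fit receives a measurement <= 0.

    Under the Rician magnitude noise model measurements are positive with
    probability one, so a nonpositive value indicates a pipeline bug rather
    than bad luck; the fit aborts instead of clipping.
    """

    def __init__(self, index: int, value: float):
        self.index = index
        self.value = value
        super().__init__(
            f"measurement {value!r} at index {index} is not positive; "
            "ln(m) is undefined (pass clip_floor to clip instead)"
        )


class OptimizationError(AdcDesignError):
    """Raised when a numeric design search fails to converge.

    Carries the best iterate found so far in ``best_b`` / ``best_value``.
    """

    def __init__(self, message: str, best_b=None, best_value=None):
        self.best_b = best_b
        self.best_value = best_value
        super().__init__(message)
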