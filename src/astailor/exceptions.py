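"""Package-specific error types."""


class AstailorError(Exception):
    """Base class for all errors raised by astailor."""


class NoSupportError(AstailorError):
    """Raised when a kernel estimator has no data mass near the requested time.

    Callers can widen the bandwidth, drop the landmark, or treat the
    estimate as unavailable.
    """


class OptimizationError(AstailorError):
    """Raised when the surrogate-loss minimization fails to converge."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
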