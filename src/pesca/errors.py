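"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, ValidationError -> 3,
CapacityError / ConvergenceError -> 4.
"""


class PescaError(Exception):
    """Base class for all package errors."""


class ConfigError(PescaError):
    """Invalid or incomplete pipeline configuration."""


class ValidationError(PescaError):
    """Input data violates a documented precondition or invariant."""


class CapacityError(PescaError):
    """A combinatorial resource (barcode space, barcode pool) is exhausted.

    Attributes
    ----------
    achieved : int
        How many items were obtained before exhaustion.
    """

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class ConvergenceError(PescaError):
    """An iterative fit failed to converge."""
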