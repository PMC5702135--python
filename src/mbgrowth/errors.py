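"""Exception hierarchy for growth-rate determination failures.

Per-well failures (no quantifiable growth, no exponential phase) are
recoverable at plate scale: they flag the well and let the batch continue.
"""


class MBGrowthError(Exception):
    """Base class for all package-specific errors."""


class InsufficientBlankWindowError(MBGrowthError):
    """Fewer than 2 usable pre-growth cycles for blank estimation."""


class NoQuantifiableGrowthError(MBGrowthError):
    """The blanked signal never exceeds the limit of quantification."""


class NoExponentialPhaseError(MBGrowthError):
    """The iterative window search shrank below the minimum size."""


class NonPositiveBiomassError(MBGrowthError):
    """Log transform requested on a window containing values <= 0."""


class DegenerateFitError(MBGrowthError):
    """Regression input is unusable (too short, constant time, ...)."""


class ConvergenceError(MBGrowthError):
    """Non-linear regression failed to converge; carries the linear fallback."""

    def __init__(self, message, fallback=None):
        super().__init__(message)
        self.fallback = fallback
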