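"""Exception types shared across the package.

Every user-facing failure mode maps to one of these so callers can
distinguish bad parameters from numerically degenerate inputs.
"""


class RetinaLNError(Exception):
    """Base class for all package errors."""


class ParameterError(RetinaLNError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(RetinaLNError, ValueError):
    """Input is structurally valid but carries no usable signal
    (all-zero filter, zero-variance trace, empty spike train, ...)."""


class IntegrationError(RetinaLNError, RuntimeError):
    """Explicit-Euler step would be unstable; re-run with a smaller dt."""


class ConditioningError(RetinaLNError, RuntimeError):
    """Spectral division is ill-posed (stimulus has no in-band power)."""
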