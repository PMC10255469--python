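"""Exception hierarchy shared across the package."""


class VadeegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VadeegError, ValueError):
    """Unknown or malformed file format."""


class SchemaError(VadeegError, ValueError):
    """Data violates a structural contract (shape, labels, NaN, ...)."""


class RangeError(VadeegError, ValueError):
    """A numeric argument or window is out of its valid range."""


class PreconditionError(VadeegError, ValueError):
    """An operation's stated precondition is not met."""


class SelectionError(VadeegError, RuntimeError):
    """Adaptive channel selection produced an empty electrode set."""


class ConvergenceError(VadeegError, RuntimeError):
    """Levenberg-Marquardt training diverged (non-finite cost).

    Carries the optimisation ``history`` recorded up to the failure.
    """

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history if history is not None else []
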