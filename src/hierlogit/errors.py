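"""Exception types shared across the package."""


class HierlogitError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(HierlogitError, ValueError):
    """An input violates a documented precondition or invariant."""


class UndefinedStatisticError(HierlogitError, ArithmeticError):
    """A diagnostic statistic is undefined for the given draws (e.g. constant chains)."""


class SamplerError(HierlogitError, RuntimeError):
    """Hard sampler failure (step-size collapse, pathological geometry)."""


class NonFiniteGradientError(HierlogitError, FloatingPointError):
    """The log-posterior gradient is non-finite; carries the offending coordinate."""

    def __init__(self, coordinate: str):
        self.coordinate = coordinate
        super().__init__(f"non-finite gradient in coordinate {coordinate!r}")
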