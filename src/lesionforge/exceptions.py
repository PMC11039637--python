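"""Exception hierarchy shared across the package."""


class LesionForgeError(Exception):
    """Base class for all package errors."""


class ValidationError(LesionForgeError, ValueError):
    """An input value violates a documented precondition or invariant."""


class StructuralError(LesionForgeError, ValueError):
    """A vector/spec/layout composition mismatch (wrong length, wrong layer kinds)."""


class UndefinedMetricError(LesionForgeError, ArithmeticError):
    """A metric's denominator is zero so the quantity is mathematically undefined."""


class StateError(LesionForgeError, RuntimeError):
    """An operation was invoked on an object in the wrong state (e.g. untrained node)."""
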