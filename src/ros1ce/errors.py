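"""Exception hierarchy shared across the package."""


class Ros1ceError(Exception):
    """Base class for all package errors."""


class InvalidCurveError(Ros1ceError):
    """A digitized curve cannot be cleaned or interpreted."""


class ValidationError(Ros1ceError):
    """Inputs violate a documented precondition."""


class NonIdentifiableError(Ros1ceError):
    """A likelihood has no information for the requested parameter (e.g. zero events)."""


class ConvergenceError(Ros1ceError):
    """The optimizer failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class AbsorbingStateError(Ros1ceError):
    """A conditional probability was requested past the support of S(t)."""
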