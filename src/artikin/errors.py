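"""Exception and warning types shared across the package."""


class ArtikinError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ArtikinError, ValueError):
    """An argument is non-finite, out of range, or otherwise unusable."""


class FrameMismatchError(ArtikinError):
    """Two transforms (or a transform and data) disagree on coordinate frames."""

    def __init__(self, expected: str | None, got: str | None, context: str = ""):
        self.expected = expected
        self.got = got
        msg = f"frame mismatch: expected {expected!r}, got {got!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class DegenerateGeometryError(ArtikinError):
    """Input geometry does not determine the requested quantity (collinear,
    coplanar, coincident...)."""


class InsufficientDataError(ArtikinError):
    """Too few (distinct) samples for the requested fit."""


class InvalidStateError(ArtikinError):
    """Operation called on an object that is not in a usable state."""


class FormatError(ArtikinError):
    """A file does not conform to the documented on-disk format."""


class SolverFailure(ArtikinError):
    """Iterative solver failed to converge.

    Carries the last iterate and residual so callers can inspect or restart.
    """

    def __init__(self, message, last_pose=None, residual=None, iterations=0):
        super().__init__(message)
        self.last_pose = last_pose
        self.residual = residual
        self.iterations = iterations


class UnresolvableInterferenceError(ArtikinError):
    """Collision interference could not be cleared within the adjustment budget."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class DomainExtrapolationWarning(UserWarning):
    """A condylar-path model was evaluated outside its fitted y-domain."""


class RegistrationQualityWarning(UserWarning):
    """Registration finished with a residual above the quality threshold."""
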