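"""Exception hierarchy for the toolkit.

Errors are deliberately fine-grained so callers (and the CLI) can map
degenerate geometry, missing landmarks and solver failures to distinct
exit codes and messages.
"""


class CanineMkoError(Exception):
    """Base class for all toolkit errors."""


class InvalidArgumentError(CanineMkoError, ValueError):
    """An argument violates a precondition (non-finite, wrong shape, ...)."""


class DegenerateGeometryError(CanineMkoError, ValueError):
    """Input points are collinear/coplanar/insufficient for the requested fit."""


class UnderdeterminedError(DegenerateGeometryError):
    """Fewer effective points than the fit requires."""


class GimbalLockError(CanineMkoError, ArithmeticError):
    """Cardan decomposition requested at |beta| = 90 deg where the first and
    third rotation axes align and the triplet is not unique."""


class MissingLandmarkError(CanineMkoError, KeyError):
    """A named anatomical landmark required for a construction is absent."""


class ConfigurationError(CanineMkoError, ValueError):
    """A marker/segment assignment or run configuration is inconsistent."""


class ModelValidityError(CanineMkoError, ValueError):
    """An assembled multibody model violates a structural invariant
    (e.g. a segment with fewer than three dynamic markers)."""


class ConvergenceError(CanineMkoError, RuntimeError):
    """An iterative fit failed to converge within its iteration cap."""

    def __init__(self, message: str, iterations: int | None = None):
        super().__init__(message)
        self.iterations = iterations


class NoEventError(CanineMkoError, ValueError):
    """Event detection found no gait events in the supplied trajectory."""


class ParseError(CanineMkoError, ValueError):
    """A data file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line
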