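"""Exception hierarchy.

All package-raised errors derive from :class:`C1RingError` so callers (and the
CLI) can distinguish computation failures from programming errors.
"""


class C1RingError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(C1RingError, ValueError):
    """Invalid input values (negative rates, non-monotone time grids, ...)."""


class GridAlignmentError(ValidationError):
    """Two objects that must share an identical time grid do not."""


class IdentifiabilityError(C1RingError):
    """A model parameter cannot be determined from the given design.

    Carries ``states``, the labels of the unidentifiable phosphoforms (when
    applicable).
    """

    def __init__(self, message, states=()):
        super().__init__(message)
        self.states = tuple(states)


class NoTransitionError(C1RingError):
    """A relaxation curve shows no resolvable amplitude (e.g. the AMP-PNP
    condition where hydrolysis-driven conversion is disabled)."""


class IntegrationError(C1RingError):
    """Numerical integration of a kinetic scheme failed."""


class FitConvergenceError(C1RingError):
    """A nonlinear least-squares fit did not converge."""


class FormatError(ValidationError):
    """A delimited-text or configuration file violates the expected layout."""


class StructureError(C1RingError):
    """Problems parsing or querying a macromolecular structure."""
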