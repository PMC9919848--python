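"""Exception hierarchy.

All package-specific failures derive from :class:`DFRETError` so callers can
catch one base class; each subclass marks a distinct contract violation.
"""


class DFRETError(Exception):
    """Base class for all dfret errors."""


class DomainError(DFRETError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class InvalidParametersError(DFRETError, ValueError):
    """Distribution or model parameters yield a non-integrable/non-finite kernel."""


class DivergenceError(DFRETError, ValueError):
    """A required integral diverges (e.g. inverse-sixth moment with rL = 0)."""


class NegativeTransferError(DFRETError, ValueError):
    """k_DA < k_D: the inferred transfer rate would be negative."""


class UndefinedDistanceError(DFRETError, ValueError):
    """No effective distance exists (zero or undefined transfer)."""


class DegenerateAmplitudeError(DFRETError, ValueError):
    """Static and dynamic limits are too close for a meaningful normalization."""


class SolverError(DFRETError, RuntimeError):
    """The PDE solver failed to converge or produced an invalid field."""


class FitRangeError(DFRETError, ValueError):
    """Profile does not span enough of the sigmoid to identify its parameters."""


class FitConvergenceError(DFRETError, RuntimeError):
    """A least-squares fit failed to converge."""


class ValidityError(DFRETError, ValueError):
    """Inputs fall outside the calibrated validity range (strict mode)."""


class StabilityError(DFRETError, ValueError):
    """A user-supplied time step violates the hazard-based stability bound."""


class UnidentifiableError(DFRETError, ValueError):
    """The observation design cannot identify the requested free parameters."""
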