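"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers can
tell a physics problem (concentration above solubility) from a data
problem (too few points) from a numerical one (no bracket for the
equilibrium root).
"""


class SorbFitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SorbFitError, ValueError):
    """An isotherm parameter violates its physical domain (e.g. Qmax <= 0)."""


class MissingContextError(SorbFitError, ValueError):
    """Temperature or solubility required by a Polanyi-potential family is absent."""


class SolubilityExceededError(SorbFitError, ValueError):
    """Equilibrium concentration exceeds the adsorbate solubility Cs."""


class TransformDomainError(SorbFitError, ValueError):
    """A data point lies outside the domain of a linearizing transform.

    Carries the indices of the offending points so the caller can report
    (or explicitly drop) them.
    """

    def __init__(self, message, indices=()):
        super().__init__(message)
        self.indices = tuple(indices)


class InsufficientDataError(SorbFitError, ValueError):
    """Fewer points than the fit's degrees of freedom require (n <= p)."""


class DegenerateDataError(SorbFitError, ValueError):
    """Regressor values are degenerate (e.g. zero variance in x)."""


class SearchBoundsError(SorbFitError, ValueError):
    """The profile-search interval is empty or excludes all feasible values."""


class FitConvergenceError(SorbFitError, RuntimeError):
    """The optimizer failed on every start."""


class EquilibrationError(SorbFitError, RuntimeError):
    """The batch mass-balance root could not be bracketed or located."""


class ConfigError(SorbFitError, ValueError):
    """A configuration file or option is malformed."""
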