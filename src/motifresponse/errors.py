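"""Exception types raised across the package."""


class MotifResponseError(Exception):
    """Base class for all package-specific errors."""


class ModelRegistryError(MotifResponseError, KeyError):
    """Unknown dynamics model name."""


class ParameterError(MotifResponseError, ValueError):
    """Missing, negative or otherwise invalid model parameter."""


class DomainError(MotifResponseError, ValueError):
    """Evaluation outside the mathematical domain (e.g. H1(x) = 0)."""


class NoSolutionError(MotifResponseError, ValueError):
    """A root-finding target lies outside the attainable range."""


class DegenerateEquilibriumError(MotifResponseError, ValueError):
    """Zero derivative of F/H1 at the equilibrium; J is undefined."""


class ConvergenceError(MotifResponseError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class RegimeValidityError(MotifResponseError, ValueError):
    """Inputs violate the validity preconditions of a closed-form result."""


class FeasibilityError(MotifResponseError, ValueError):
    """Requested construction is combinatorially infeasible."""
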