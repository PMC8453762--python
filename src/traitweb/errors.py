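"""Exception and warning types shared across the package."""


class TraitwebError(Exception):
    """Base class for all package-specific errors."""


class InvalidVarianceError(TraitwebError, ValueError):
    """Raised when a trait variance is negative."""


class InvalidKernelError(TraitwebError, ValueError):
    """Raised when kernel parameters violate their positivity constraints."""


class InvalidThresholdError(TraitwebError, ValueError):
    """Raised when a link-strength threshold is negative."""


class IncompatibleProfilesError(TraitwebError, ValueError):
    """Raised when two intake profiles do not share the same prey id set."""


class InvalidStateError(TraitwebError, ValueError):
    """Raised when population densities are negative."""


class InfeasibleEquilibriumError(TraitwebError, ValueError):
    """Raised when an operation requires a feasible coexistence equilibrium."""


class InfeasibleResidentError(InfeasibleEquilibriumError):
    """Raised when a resident genotype cannot maintain a feasible equilibrium."""


class NoViableGenotypeError(TraitwebError, ValueError):
    """Raised when no genotype in a panel has a feasible equilibrium."""


class OutOfRangeError(TraitwebError, ValueError):
    """Raised when a temperature lies outside an environment's declared range."""


class InsufficientDesignError(TraitwebError, ValueError):
    """Raised when a variance decomposition grid has fewer than 2 levels on an axis."""


class DegenerateRangeError(TraitwebError, ValueError):
    """Raised when feasibility rejection sampling rejects more than 99% of draws."""


class NumericalFailureError(TraitwebError, RuntimeError):
    """Raised when quadrature or ODE integration produces non-finite output."""


class ConfigError(TraitwebError, ValueError):
    """Raised on configuration schema violations; lists offending keys."""


class ParameterFloorWarning(UserWarning):
    """Emitted when a reaction-norm evaluation is floored at the positivity floor."""
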