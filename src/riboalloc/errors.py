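"""Typed exceptions.

Infeasible steady states and solver failures raise typed errors rather than
returning NaN, so that parameter scans fail loudly at the offending point.
"""


class RiboallocError(Exception):
    """Base class for all package errors."""


class DomainError(RiboallocError, ValueError):
    """An input lies outside the physical domain of an operation."""


class InfeasibleSteadyStateError(RiboallocError):
    """The requested allocation/rate combination admits no steady state."""


class ConvergenceError(RiboallocError):
    """A steady-state search did not converge within its horizon."""


class IntegrationError(RiboallocError):
    """The ODE integrator failed or produced an unphysical state."""


class ChargingSingularityError(RiboallocError):
    """The tRNA charging balance is undefined (uncharged pool is zero)."""


class ConfigError(RiboallocError, ValueError):
    """A run configuration is missing keys or fails validation."""
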