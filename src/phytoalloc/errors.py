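"""Typed errors raised by the forward model and chemostat layer.

All inherit from :class:`PhytoAllocError` so callers (notably the fitting
machinery, which converts failures into a finite penalty) can catch the whole
family with one clause.
"""


class PhytoAllocError(Exception):
    """Base class for all package-specific errors."""


class DomainError(PhytoAllocError, ValueError):
    """An input is outside its mathematical domain (e.g. negative light)."""


class SingularLightError(DomainError):
    """Chl:C is undefined at zero photosynthesis (I = 0 implies v_I = 0)."""


class InfeasibleAllocationError(PhytoAllocError):
    """The requested growth rate cannot be met by the carbon budget.

    Raised when the quadratic for the light-dependent maximum growth rate has
    no positive root, or when carbon-budget closure would require negative
    carbon storage.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class WashoutError(PhytoAllocError):
    """Dilution rate exceeds the maximum growth rate at the given light.

    Carries ``mu_max`` so callers can report how far above the limit the
    requested dilution rate was.
    """

    def __init__(self, d: float, mu_max: float):
        super().__init__(
            f"dilution rate D={d:g} d^-1 exceeds mu_max={mu_max:g} d^-1: washout"
        )
        self.d = d
        self.mu_max = mu_max


class DegenerateFeedError(DomainError):
    """Both feed concentrations are zero; limitation is undefined."""


class ConsistencyError(PhytoAllocError):
    """An internal steady-state bookkeeping identity was violated."""


class ConfigError(PhytoAllocError, ValueError):
    """A run/fit configuration is malformed or incomplete."""
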