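"""Exception hierarchy for butyflux."""


class ButyfluxError(Exception):
    """Base class for all package errors."""


class FormulaError(ButyfluxError):
    """Malformed molecular formula string or unsupported element."""


class BalanceInfeasibleError(ButyfluxError):
    """No non-negative solution to the elemental balance."""

    def __init__(self, message, violated_elements=()):
        super().__init__(message)
        self.violated_elements = tuple(violated_elements)


class BalanceAmbiguityError(ButyfluxError):
    """Balance solution space is under-determined with no integer-minimal member."""

    def __init__(self, message, free_direction=None):
        super().__init__(message)
        self.free_direction = free_direction


class PathwayValidationError(ButyfluxError):
    """Pathway config violates carbon conservation or reachability."""


class DegenerateFluxError(ButyfluxError):
    """Flux configuration yields a singular acetyl-CoA fixed point."""


class ConvergenceError(ButyfluxError):
    """Iterative solver failed to converge within the iteration cap."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class UndefinedFractionsError(ButyfluxError):
    """Class fractions are undefined (no labelled mass at the observed positions)."""


class NoGrowthError(ButyfluxError):
    """Growth curve shows no measurable growth; Gompertz fit refused."""
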