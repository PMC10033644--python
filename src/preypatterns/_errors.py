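"""Exception hierarchy shared across the package."""


class PreyPatternsError(Exception):
    """Base class for all package errors."""


class DomainError(PreyPatternsError, ValueError):
    """A parameter or state violates the model's admissible domain."""


class UnsupportedVariantError(DomainError):
    """The requested operation is not defined for this model variant."""


class NumericalInstabilityError(PreyPatternsError, RuntimeError):
    """A simulation or integration blew up or produced non-finite values."""


class CFLViolationError(DomainError, NumericalInstabilityError):
    """Time step too large for the explicit diffusion stencil."""


class BranchDiscontinuityError(PreyPatternsError, RuntimeError):
    """The tracked equilibrium branch collided with another inside the bracket."""


class NotASaddleError(PreyPatternsError, ValueError):
    """Separatrix construction requires a saddle equilibrium."""


class NoFoldError(PreyPatternsError, RuntimeError):
    """No fold bifurcation inside the supplied bracket."""


class UnknownFixtureError(PreyPatternsError, KeyError):
    """Requested fixture key is not registered."""
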