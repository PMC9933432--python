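"""Exception hierarchy."""


class GCNCMCError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GCNCMCError, ValueError):
    """Invalid system, region, protocol or campaign configuration."""


class DomainError(GCNCMCError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SingularityError(GCNCMCError, ArithmeticError):
    """A bare Coulomb interaction was requested at zero separation."""


class ConstraintError(GCNCMCError, RuntimeError):
    """Iterative constraint projection failed to converge."""


class IntegrationError(GCNCMCError, RuntimeError):
    """Dynamics produced non-finite forces or coordinates."""


class ParseError(GCNCMCError, ValueError):
    """A structure or parameter file could not be parsed."""
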