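"""Exception hierarchy shared across the simulator modules."""


class UlcerSimError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(UlcerSimError):
    """A surface or parameter specification violates its invariants."""


class RegularityError(UlcerSimError):
    """The parametrization fails the regular-surface condition (EG - F^2 <= 0
    or a degenerate normal) at a requested point."""


class QuadratureError(UlcerSimError):
    """Surface quadrature failed to converge within the refinement cap."""


class UnphysicalStrainError(UlcerSimError):
    """A linear-elastic strain of magnitude >= 1 was requested."""


class SingularParameterError(UlcerSimError):
    """A formula was evaluated at a parameter that makes it singular."""


class UnsupportedOperationError(UlcerSimError):
    """The operation needs derivative access the surface does not provide."""


class IntegrationError(UlcerSimError):
    """The ODE solver failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class ConfigError(UlcerSimError):
    """A scenario configuration is malformed; names the offending keys."""
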