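"""Exception hierarchy for the knee-simulation pipeline.

Distinct classes let callers (and the CLI exit-code mapping) separate
configuration problems from numerical failures and I/O problems.
"""


class KneesimError(Exception):
    """Base class for all package errors."""


class ParameterError(KneesimError, ValueError):
    """A parameter is outside its documented range."""


class ConfigError(KneesimError):
    """Configuration file could not be parsed or validated."""

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        super().__init__(message if field is None else f"{field}: {message}")


class GeometryError(KneesimError):
    """Degenerate or unresolvable geometric construction."""


class LookupError_(KneesimError, KeyError):
    """Unknown site, bundle, muscle or group name."""


class AlignmentError(KneesimError):
    """Two sampled series do not share a sampling grid."""


class InfeasibleError(KneesimError):
    """The muscle-force optimization has no feasible point."""


class IntegrationError(KneesimError):
    """Adaptive integration failed (step-size underflow)."""

    def __init__(self, message: str, time: float | None = None):
        self.time = time
        super().__init__(message if time is None else f"t={time:.4f} s: {message}")


class EquilibriumError(KneesimError):
    """Quasi-static equilibrium search did not converge."""


class ResultIOError(KneesimError):
    """Reading or writing a results file failed."""
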