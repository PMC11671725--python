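"""Exception hierarchy for n2opart."""


class N2OPartError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(N2OPartError, ValueError):
    """An argument violates a physical or schema precondition."""


class DomainError(N2OPartError, ValueError):
    """A value lies outside the mathematical domain of an operation
    (e.g. a product ratio outside (0, 1] fed to a logarithm)."""


class UndefinedRatioError(N2OPartError, ZeroDivisionError):
    """Both fluxes of a product ratio are zero, so the ratio is undefined."""


class NoEmissionError(N2OPartError, ValueError):
    """Background subtraction requested with no net emission
    (mixture concentration not above background)."""


class BelowDetectionError(N2OPartError, RuntimeError):
    """Isotopologue excess is below the instrument detection limit."""


class InconsistentExcessError(N2OPartError, RuntimeError):
    """Isotopologue excesses are not jointly consistent with any
    two-pool mixture (pool-derived fraction outside [0, 1])."""


class DegenerateSystemError(N2OPartError, RuntimeError):
    """The 4x4 mixing system is singular or numerically degenerate."""


class NoAcceptedDrawsError(N2OPartError, RuntimeError):
    """The constrained Monte Carlo run accepted zero draws.

    Carries per-constraint failure counts in :attr:`diagnostics`.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SchemaError(N2OPartError, ValueError):
    """An input table does not match the documented schema."""
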