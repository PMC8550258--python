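"""Exception hierarchy shared across the package."""


class ProteinTrajError(Exception):
    """Base class for all package errors."""


class ParameterError(ProteinTrajError, ValueError):
    """A distribution or model parameter is outside its domain."""


class DomainError(ProteinTrajError, ValueError):
    """An evaluation point lies outside the fitted/declared time domain."""


class InsufficientDataError(ProteinTrajError, ValueError):
    """Too few observations for the requested fit."""


class RankDeficiencyError(ProteinTrajError, ValueError):
    """Unpenalized design is rank deficient."""


class FitFailureError(ProteinTrajError, RuntimeError):
    """A likelihood became non-finite or a fit could not proceed."""


class ApproximationError(ProteinTrajError, RuntimeError):
    """Polynomial approximation failed to reach the R^2 threshold."""


class SchemaError(ProteinTrajError, ValueError):
    """A serialized artifact violates the expected schema."""


class ValidationError(ProteinTrajError, ValueError):
    """Invalid user input (CSV rows, configuration)."""


class DesignError(ProteinTrajError, ValueError):
    """Infeasible synthetic study design."""
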