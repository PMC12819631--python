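"""Exception hierarchy shared across the package."""


class SelhazError(Exception):
    """Base class for all package errors."""


class ConfigError(SelhazError):
    """Invalid or infeasible configuration."""


class ScheduleError(ConfigError):
    """Unknown (service_type, tier) pair or malformed reimbursement entry."""


class DomainError(SelhazError):
    """Argument outside the mathematical domain of an operation."""


class DegenerateSampleError(SelhazError):
    """A sample with zero spread where spread is required (bandwidths, moments)."""


class StratumSkippedError(SelhazError):
    """Too few records to fit a density surface for a stratum."""


class InfeasibleRecordError(SelhazError):
    """Residual consumption non-positive somewhere the density puts mass."""


class EstimationError(SelhazError):
    """An estimator could not produce a result (all grid nodes infeasible, ...)."""
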