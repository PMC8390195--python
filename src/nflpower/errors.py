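"""Exception hierarchy shared across the package."""


class NflPowerError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NflPowerError):
    """A configuration problem: missing column, bad mapping, invalid option."""


class CohortValidationError(NflPowerError):
    """Structural cohort problem that prevents construction (e.g. orphan visits)."""


class InsufficientDataError(NflPowerError):
    """Too few patients / visits / distinct time points for the requested analysis."""


class DomainError(NflPowerError):
    """An argument outside the mathematical domain of an operation."""


class UndefinedMetricError(NflPowerError):
    """A metric whose denominator is zero for the given data."""
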