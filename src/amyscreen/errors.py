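"""Exception types raised across the package.

All inherit from :class:`ValueError` so callers that do not care about the
distinction can catch a single base class.
"""


class AmyscreenError(ValueError):
    """Base class for package-specific errors."""


class InvalidSummaryError(AmyscreenError):
    """Quartile summary is non-positive or mis-ordered."""


class DegenerateDataError(AmyscreenError):
    """Input data cannot support the requested fit (e.g. all values identical)."""


class InvalidRecordError(AmyscreenError):
    """A participant record violates an invariant (names the offending row)."""


class UndefinedRocError(AmyscreenError):
    """ROC analysis requested with only one outcome class present."""


class InfeasibleDesignError(AmyscreenError):
    """Screening design cannot be solved (e.g. zero sensitivity)."""


class ConfigError(AmyscreenError):
    """Analysis or simulation configuration is invalid."""
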