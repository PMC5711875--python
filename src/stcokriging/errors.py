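"""Exception hierarchy for stcokriging.

All package-specific failures derive from :class:`STCKError` so callers can
catch one base class; subclasses distinguish configuration mistakes from
data problems and numerical breakdown.
"""


class STCKError(Exception):
    """Base class for all stcokriging errors."""


class ConfigurationError(STCKError):
    """Invalid configuration: missing column, unknown variable, bad bounds."""


class ParseError(STCKError):
    """Malformed input file (non-numeric coordinate or value, bad schema)."""


class DuplicateRecordError(STCKError):
    """Two records share the same (point, variable) key."""


class DomainError(STCKError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class InsufficientDataError(STCKError):
    """Too few samples to perform the requested computation."""


class InsufficientOverlapError(InsufficientDataError):
    """Too few co-located observations of a variable pair."""


class SingularSystemError(STCKError):
    """The kriging system is singular or numerically ill-conditioned."""
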