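"""Exception hierarchy for marshcarbon.

All package errors derive from :class:`MarshCarbonError` so callers can catch
one base class at pipeline boundaries.
"""


class MarshCarbonError(Exception):
    """Base class for all marshcarbon errors."""


class SchemaError(MarshCarbonError):
    """An input table is missing required columns or has an unusable layout."""


class ValidationError(MarshCarbonError):
    """A value violates a domain invariant (negative salinity, zero area, ...)."""


class EmptyWindowError(MarshCarbonError):
    """No observations fall inside the requested pre/post window."""


class UnitError(MarshCarbonError):
    """Quantities with incompatible mass bases were combined without conversion."""


class CoverageError(MarshCarbonError):
    """A valuation schedule does not cover the requested year window."""


class ConfigError(MarshCarbonError):
    """A configuration entry (GWP row, emission factor) is inconsistent."""


class ConsistencyError(MarshCarbonError):
    """A synthetic scenario's declared ground truth contradicts its parameters."""
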