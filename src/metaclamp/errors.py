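"""Exception hierarchy.

All package errors derive from :class:`MetaclampError` so callers can catch
one base class; the three subclasses separate bad configuration, bad input
data, and estimation failures (e.g. steady state never reached).
"""


class MetaclampError(Exception):
    """Base class for all metaclamp errors."""


class ConfigurationError(MetaclampError):
    """A configuration value is invalid; the message names the field."""


class DataError(MetaclampError):
    """Input data violate a precondition (missing point, bad units, ...)."""


class EstimationError(MetaclampError):
    """An estimator cannot produce a result from otherwise valid data."""
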