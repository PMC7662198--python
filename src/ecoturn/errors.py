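"""Exception hierarchy for the ecoturn pipeline.

All errors raised by this package derive from :class:`EcoturnError`, so
callers can distinguish pipeline failures from programming errors.
"""


class EcoturnError(Exception):
    """Base class for all ecoturn errors."""


class ConfigurationError(EcoturnError):
    """A config file, column map or synonym map is malformed."""


class ValidationError(EcoturnError):
    """Input data violates a precondition (e.g. negative abundance)."""


class UndefinedMetricError(EcoturnError):
    """A metric is mathematically undefined on the given input
    (empty assemblage, zero total abundance, zero mean, n too small)."""


class InsufficientDataError(EcoturnError):
    """Not enough observations to perform a fit or detection."""
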