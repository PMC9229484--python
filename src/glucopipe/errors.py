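"""Exception hierarchy for glucopipe.

All errors derive from :class:`GlucopipeError` so callers can catch the
package's failures with one clause; the subclasses distinguish bad
configuration, bad data, bad call parameters, and object-state misuse.
"""


class GlucopipeError(Exception):
    """Base class for all glucopipe errors."""


class ConfigurationError(GlucopipeError, ValueError):
    """A config object violates its invariants (e.g. negative half-width)."""


class ParameterError(GlucopipeError, ValueError):
    """A function argument is out of its admissible range."""


class DataError(GlucopipeError, ValueError):
    """Input data have the wrong shape, axis, or values."""


class InsufficientPeaksError(DataError):
    """Fewer than two pulse peaks were found; statistics are undefined."""


class StateError(GlucopipeError, RuntimeError):
    """An object was used before being fitted/initialized."""
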