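"""Exception hierarchy shared across the toolbox.

All exceptions derive from :class:`SpikeSpatialError` so callers can catch
everything the library raises with a single handler; batch drivers rely on
this to isolate per-unit failures.
"""


class SpikeSpatialError(Exception):
    """Base class for all library errors."""


class InvalidArgumentError(SpikeSpatialError, ValueError):
    """A parameter violates a documented precondition."""


class InsufficientDataError(SpikeSpatialError):
    """Not enough spikes/samples/events to compute the statistic."""


class MissingDataError(SpikeSpatialError):
    """A required channel (e.g. waveforms) is absent from the input."""


class FormatError(SpikeSpatialError):
    """A file does not conform to the documented on-disk layout."""


class UndefinedStatisticError(SpikeSpatialError):
    """The statistic is mathematically undefined for this input
    (e.g. zero mean rate, zero variance)."""


class FitError(SpikeSpatialError):
    """A nonlinear fit failed to converge after all restarts."""
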