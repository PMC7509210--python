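"""Exception hierarchy used across the package.

Every error raised by steerlimb derives from :class:`SteerlimbError`, so
callers (and the batch driver) can isolate failures per trial without
catching unrelated programming errors.
"""


class SteerlimbError(Exception):
    """Base class for all steerlimb errors."""


class FormatError(SteerlimbError):
    """A file does not conform to the expected layout (missing column, bad metadata key)."""


class TimingError(SteerlimbError):
    """The time column of a trial is not uniformly sampled."""


class DataError(SteerlimbError):
    """A data series contains invalid values (NaN/inf)."""


class ConfigError(SteerlimbError):
    """A simulation or run configuration violates its constraints."""


class ParameterError(SteerlimbError):
    """An analysis parameter is inconsistent with the data (e.g. filter band vs fs)."""


class LengthError(SteerlimbError):
    """A series is too short for the requested operation."""


class CoverageError(SteerlimbError):
    """Not enough labeled samples in a steering direction to run an analysis."""


class DegenerateInputError(SteerlimbError):
    """Input is degenerate for the operation (all-zero envelope, zero variance, ...)."""


class PairingError(SteerlimbError):
    """Paired samples have mismatched lengths."""


class SampleSizeError(SteerlimbError):
    """Too few subjects/samples for a statistical test."""


class UsageError(SteerlimbError):
    """The API was called with structurally invalid arguments (empty list, mixed kinds)."""


class DomainError(SteerlimbError):
    """A scalar argument is outside its mathematical domain."""


class EmptySegmentsWarning(UserWarning):
    """No steering episode exceeded the dead-band/duration thresholds."""


class BoundaryWarning(UserWarning):
    """A lag optimum landed on the edge of the search window."""
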