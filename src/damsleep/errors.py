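"""Exception hierarchy shared across the package."""


class DamSleepError(Exception):
    """Base class for all damsleep errors."""


class MonitorParseError(DamSleepError):
    """A monitor file row could not be parsed (names the offending line)."""


class AlignmentError(DamSleepError):
    """Timestamps are non-monotone or have gaps beyond the repairable limit."""


class DataError(DamSleepError):
    """Input data violate a structural invariant (e.g. negative counts)."""


class WindowError(DamSleepError):
    """The recording is too short for the requested analysis window."""


class ParameterError(DamSleepError):
    """A user-supplied parameter is out of its valid range."""


class FitError(DamSleepError):
    """A model fit failed to converge."""
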