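"""Exception hierarchy for the wheelergo pipeline.

Analysis-stage failures are data, not crashes: the cohort runner catches
``WheelErgoError`` per participant and records the failure, so a single bad
trace never aborts a batch.
"""


class WheelErgoError(Exception):
    """Base class for all wheelergo errors."""


class TraceFormatError(WheelErgoError):
    """A trace file or trace construction violates the format contract."""


class InsufficientDataError(WheelErgoError):
    """A trace is too short for the requested window or filter."""


class InvalidConfigurationError(WheelErgoError):
    """A parameter combination is physically or numerically invalid."""


class DegenerateTraceError(WheelErgoError):
    """A trace is structurally fine but its content makes a metric undefined."""


class NoResultError(WheelErgoError):
    """No usable trial/trace remains for a participant (e.g. hardware failure)."""


class CalibrationError(WheelErgoError):
    """The simulator cannot realize the requested target output."""
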