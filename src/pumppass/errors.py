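"""Exception hierarchy shared across the pipeline stages."""


class PumppassError(Exception):
    """Base class for all package errors."""


class SignalError(PumppassError):
    """Errors raised while processing pressure traces."""


class AllChannelsInvalid(SignalError):
    """Every pressure channel was flagged as an outlier channel."""


class NoInjection(SignalError):
    """The trace never exceeds the injection pressure threshold."""


class NoNadir(SignalError):
    """No sample in the search window meets the nadir change criterion."""


class NoExit(SignalError):
    """No terminal plateau could be found after the nadir."""


class BadWindow(SignalError):
    """Invalid smoothing window (even, too short, or shorter than the order)."""


class InvalidMarks(SignalError):
    """Passage marks are inconsistent (ordering or out of range)."""


class NonPositivePressure(SignalError):
    """A pressure that must be positive is zero or negative."""


class EmptyScenario(PumppassError):
    """An ensemble/scenario grouping contains no deployments."""


class StrainError(PumppassError):
    """Errors in the shear-strain estimation stage."""


class OutOfRange(StrainError):
    """Input outside the validity range of a correlation."""


class MissingChannel(StrainError):
    """Fewer than three valid channels, or the center channel is unknown."""


class NotCalibrated(StrainError):
    """The fluid context has no calibrated characteristic length."""


class CodingError(PumppassError):
    """Errors in fish record coding."""


class UnknownCode(CodingError):
    """An injury code outside the standardized list."""


class MissingStartCount(CodingError):
    """A scenario lacks an intended (start) fish count."""


class EmptyClass(CodingError):
    """An injury class with no observations was requested."""


class StatsError(PumppassError):
    """Errors in the statistics layer."""


class InsufficientData(StatsError):
    """Not enough groups/observations for the requested test."""


class CompleteSeparation(StatsError):
    """A stratum with a single outcome value makes coefficients diverge."""


class SingleCategory(StatsError):
    """Multinomial response with fewer than two observed categories."""


class MissingScenario(StatsError):
    """A required scenario level is absent from the data."""


class BadScenario(PumppassError):
    """Invalid synthetic-data scenario specification."""


class IOErrorPumppass(PumppassError):
    """Errors reading or writing pipeline files."""


class ParseError(IOErrorPumppass):
    """Malformed input file; message carries the offending line number."""


class MissingMeta(IOErrorPumppass):
    """Deployment metadata absent or incomplete."""


class MissingStage(IOErrorPumppass):
    """Report assembly is missing a required stage output."""
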