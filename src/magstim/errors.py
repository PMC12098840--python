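"""Exception hierarchy shared across the toolkit."""


class MagstimError(Exception):
    """Base class for all magstim errors."""


class ConfigurationError(MagstimError):
    """Invalid geometry, discretization, or run configuration."""


class FieldSingularityError(MagstimError):
    """Field evaluation requested on (or numerically on) a current filament."""


class EmptyRegionError(MagstimError):
    """An evaluation region contains too few field samples."""


class ProtocolError(MagstimError):
    """A stimulation protocol violates its timing invariants."""


class StreamTruncationError(MagstimError):
    """An input stream ends before the protocol it must cover."""


class UndefinedStatisticError(MagstimError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class TrackingError(MagstimError):
    """Invalid frame, ROI, or detection configuration."""
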