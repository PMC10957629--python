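"""Exception hierarchy shared across the package."""


class PrandialError(Exception):
    """Base class for all package errors."""


class FormatError(PrandialError):
    """Input file does not follow the expected tabular layout."""


class ValidationError(PrandialError):
    """Input data violates a structural invariant (e.g. duplicate samples)."""


class ConfigurationError(PrandialError):
    """A configuration value is inconsistent or refers to something absent."""


class UnfittableSeriesError(PrandialError):
    """A time series has too few usable points for curve fitting."""


class PipelineError(PrandialError):
    """A pipeline stage failed; the message names the stage and the cause."""
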