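"""Exception hierarchy used across the pipeline and mapped to CLI exit codes."""


class WavetraceError(Exception):
    """Base class for all package errors."""


class ConfigError(WavetraceError):
    """Invalid configuration or parameters (CLI exit code 2)."""


class DataError(WavetraceError):
    """Invalid or degenerate input data (CLI exit code 3)."""


class GeometryError(DataError):
    """Degenerate scan geometry (collinear circle points, zero-length arcs, ...)."""


class FitError(DataError):
    """A model fit failed to converge or the design is rank deficient."""
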