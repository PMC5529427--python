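"""Exception hierarchy shared across the pipeline."""


class ClptelError(Exception):
    """Base class for all package errors."""


class ParameterError(ClptelError, ValueError):
    """Invalid simulation, criteria or cost parameters."""


class TraceError(ClptelError, ValueError):
    """A telemetry trace violates its structural invariants."""


class DetectionError(ClptelError, ValueError):
    """The deterioration criterion is undefined for the given trace."""


class AnalysisError(ClptelError, ValueError):
    """Cohort analysis cannot proceed (e.g. no analyzable mice)."""


class CapabilityError(ClptelError, RuntimeError):
    """Exact enumeration would exceed the configured enumeration budget."""


class ParseError(ClptelError, ValueError):
    """A delimited input file violates its schema."""
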