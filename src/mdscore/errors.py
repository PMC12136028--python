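"""Exception hierarchy shared across the package."""


class MdsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MdsError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(MdsError, ValueError):
    """An input table does not conform to the documented schema."""


class DegenerateDataError(MdsError, ValueError):
    """Data on which the requested statistic is undefined (single class,
    empty stratum, constant values, ...)."""


class ConvergenceError(MdsError, RuntimeError):
    """An iterative fit failed to converge; message carries diagnostics."""


class PipelineError(MdsError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
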