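"""Exception hierarchy shared across the package."""


class PirnatoolsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PirnatoolsError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(PirnatoolsError, ValueError):
    """Inconsistent configuration, e.g. a profile naming features absent from the library."""


class ParseError(PirnatoolsError, ValueError):
    """Malformed input file; the message names the offending record."""


class NormalizationError(PirnatoolsError, ValueError):
    """Normalization requested with an unusable denominator."""


class PipelineStageError(PirnatoolsError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
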