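"""Exception hierarchy used across the package."""


class NacfamError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NacfamError):
    """A configuration value is out of range or inconsistent."""


class InputError(NacfamError):
    """An input object violates a precondition (ragged alignment, bad coordinates, ...)."""


class ParseError(NacfamError):
    """A file could not be parsed; the message names the offending line where possible."""


class PipelineError(NacfamError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
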