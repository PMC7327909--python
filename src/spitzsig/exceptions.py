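"""Exception hierarchy shared across the pipeline."""


class SpitzsigError(Exception):
    """Base class for all package errors."""


class FormatError(SpitzsigError, ValueError):
    """Malformed input file (bad cell, duplicate id, short GMT line, ...)."""


class ParameterError(SpitzsigError, ValueError):
    """Invalid argument or configuration value."""


class InsufficientReplicationError(SpitzsigError, ValueError):
    """A group has too few samples for the requested fit."""


class PipelineStageError(SpitzsigError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
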