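"""Exception hierarchy shared across the package."""


class MrpipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrpipeError):
    """A file, column mapping, or run configuration is unusable."""


class ValidationError(MrpipeError):
    """Input data violates a documented invariant."""


class InsufficientInstrumentsError(MrpipeError):
    """An estimator was called with fewer instruments than it supports."""


class PipelineError(MrpipeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
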