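"""Exception types shared across the pipeline stages."""


class EpnMethylError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpnMethylError):
    """A cohort or run configuration field is invalid; names the field."""


class ValidationError(EpnMethylError):
    """An input violates a documented precondition."""


class DegenerateFitError(EpnMethylError):
    """All observations identical after clipping; a beta fit is undefined."""


class NoCrossoverError(EpnMethylError):
    """The two class densities never cross (or cross ambiguously) in (0, 100)."""


class UnresolvedLabelError(EpnMethylError):
    """Two clusters have identical mean marker methylation; PFA/PFB cannot be assigned."""


class PipelineError(EpnMethylError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
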