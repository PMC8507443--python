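"""Exception hierarchy for the segmentation pipeline."""


class PelvisegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PelvisegError):
    """A file or series could not be interpreted (bad/inconsistent metadata)."""


class ParameterError(PelvisegError, ValueError):
    """A pipeline or phantom parameter violates an invariant."""


class AlignmentError(PelvisegError, ValueError):
    """Two grids that must share shape/geometry do not."""


class PhantomSpecError(ParameterError):
    """A phantom specification is invalid or geometrically impossible."""


class EmptyBodyError(PelvisegError):
    """No voxel above the air threshold: there is no body to segment."""


class PipelineStageError(PelvisegError):
    """An error raised inside ``run_pipeline``, tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
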