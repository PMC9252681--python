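"""Named error conditions raised across the segmentation pipeline."""


class HybridsegError(Exception):
    """Base class for all package-specific errors."""


class NonVolumeDataError(HybridsegError):
    """The on-disk data block is not a 3D scalar grid."""


class HeaderError(HybridsegError):
    """The NIfTI header could not be read or is inconsistent."""


class ShapeMismatchError(HybridsegError):
    """Volumes (or masks) that must share a grid do not."""


class DuplicateModalityError(HybridsegError):
    """Two stack members carry the same modality tag."""


class FilterRadiusError(HybridsegError):
    """Median-filter window exceeds the volume extent."""


class HistogramError(HybridsegError):
    """Histogram construction or use failed (non-finite values, too few levels)."""


class ClusterCountError(HybridsegError):
    """Requested cluster count exceeds the number of distinct gray levels."""


class EmptyMaskError(HybridsegError):
    """A mask required to be nonempty (and not full) is empty or full."""


class InterfaceCollapseError(HybridsegError):
    """The level-set zero crossing vanished during evolution."""


class EvolutionBlowupError(HybridsegError):
    """Non-finite values appeared mid-evolution (time step too large)."""


class ConfigError(HybridsegError):
    """Pipeline configuration failed validation.

    ``problems`` lists one message per offending field.
    """

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class StageError(HybridsegError):
    """A pipeline stage failed; carries the stage name plus the cause."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
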