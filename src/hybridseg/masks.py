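"""Binary 3D masks shared by the clustering, thresholding and level-set stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NonVolumeDataError

__all__ = ["Mask"]


@dataclass
class Mask:
    """A binary 3D grid with its voxel spacing.

    ``data`` is stored as bool; ``voxel_count`` is the number of foreground
    voxels.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise NonVolumeDataError(f"mask must be 3D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise NonVolumeDataError("mask values must be strictly binary")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.data & other.data, self.spacing)

    def __invert__(self) -> "Mask":
        return Mask(~self.data, self.spacing)
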