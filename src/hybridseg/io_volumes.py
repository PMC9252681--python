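"""Reading, writing and stacking co-registered 3D volumes.

Volumes are plain scalar grids with voxel spacing and a free-text modality
tag.  On disk the package speaks NIfTI-1 (``.nii`` / ``.nii.gz``) through
nibabel, storing data as 32-bit floats so round trips are exact at that
precision.  Array axes map to file axes in order; no reorientation to
anatomical axes is performed, and volumes are assumed pre-registered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .errors import (
    DuplicateModalityError,
    HeaderError,
    NonVolumeDataError,
    ShapeMismatchError,
)

__all__ = ["Volume3D", "ModalityStack", "read_volume", "write_volume", "make_stack"]


@dataclass
class Volume3D:
    """One scalar 3D image.

    Parameters
    ----------
    data:
        3D array of finite scalars (stored as float32).
    spacing:
        Physical voxel size per axis in mm; strictly positive.
    modality:
        Free-text tag such as ``"T1WI"``, ``"T2WI"`` or ``"FLAIR"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float32)
        if arr.ndim != 3:
            raise NonVolumeDataError(
                f"expected a 3D data block, got {arr.ndim}D shape {arr.shape}"
            )
        if any(s < 1 for s in arr.shape):
            raise NonVolumeDataError(f"every dimension must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise NonVolumeDataError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise HeaderError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        self.data = arr
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "Volume3D":
        """New volume on the same grid with replaced voxel values."""
        return Volume3D(data, self.spacing, self.modality if modality is None else modality)


@dataclass
class ModalityStack:
    """Ordered, shape-aligned collection of single-modality volumes."""

    volumes: list[Volume3D]
    names: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self):
        return iter(self.volumes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volumes[0].spacing


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI file into a :class:`Volume3D`.

    The modality tag defaults to the filename stem.  Raises
    :class:`FileNotFoundError` for a missing file, :class:`NonVolumeDataError`
    for a non-3D data block and :class:`HeaderError` for an unreadable header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
    except Exception as exc:  # nibabel raises a zoo of format errors
        raise HeaderError(f"cannot read NIfTI header of {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise NonVolumeDataError(
            f"{path} holds a {data.ndim}D data block; expected a single 3D frame"
        )
    stem = path.name
    for suffix in (".gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return Volume3D(data, tuple(float(z) for z in zooms[:3]), modality=stem)


def write_volume(volume: Volume3D, path: str | Path) -> None:
    """Write a volume as float32 NIfTI-1; inverse of :func:`read_volume`."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def make_stack(volumes: Sequence[Volume3D]) -> ModalityStack:
    """Validate and assemble a multimodal stack, preserving input order."""
    vols = list(volumes)
    if not vols:
        raise ValueError("a stack needs at least one volume")
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape:
            raise ShapeMismatchError(f"shape mismatch: {v.shape} vs {ref.shape}")
        if not np.allclose(v.spacing, ref.spacing):
            raise ShapeMismatchError(f"spacing mismatch: {v.spacing} vs {ref.spacing}")
    names = [v.modality for v in vols]
    if len(set(names)) != len(names):
        raise DuplicateModalityError(f"duplicate modality names in {names}")
    return ModalityStack(vols, names)
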