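"""Segmentation agreement metrics against ground truth."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .errors import ShapeMismatchError
from .masks import Mask

__all__ = ["EvalReport", "dice", "jaccard", "hausdorff", "evaluate"]


@dataclass
class EvalReport:
    """Overlap and distance metrics for one predicted/truth mask pair.

    ``volume_error`` is the signed relative volume difference
    (|pred| - |truth|) / |truth|.  ``hausdorff`` is the maximum symmetric
    surface distance in voxels (None when either mask is empty);
    ``hausdorff_mm`` additionally scales by the voxel spacing.
    """

    dice: float
    jaccard: float
    volume_error: float
    hausdorff: float | None = None
    hausdorff_mm: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _check_shapes(a: Mask, b: Mask) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dice(a: Mask, b: Mask) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    _check_shapes(a, b)
    na, nb = a.voxel_count, b.voxel_count
    if na + nb == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (na + nb)


def jaccard(a: Mask, b: Mask) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    _check_shapes(a, b)
    union = int((a.data | b.data).sum())
    if union == 0:
        return 1.0
    inter = int((a.data & b.data).sum())
    return inter / union


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def hausdorff(a: Mask, b: Mask, spacing: tuple[float, float, float] | None = None) -> float | None:
    """Maximum symmetric surface distance between two nonempty masks.

    Computed from Euclidean distance transforms of the surface voxels;
    returns None when either mask is empty.  ``spacing`` switches the
    distances to physical units.
    """
    _check_shapes(a, b)
    if a.voxel_count == 0 or b.voxel_count == 0:
        return None
    sa, sb = _surface(a.data), _surface(b.data)
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    return float(max(dt_b[sa].max(), dt_a[sb].max()))


def evaluate(pred: Mask, truth: Mask) -> EvalReport:
    """All metrics for one prediction; Hausdorff omitted on empty masks."""
    _check_shapes(pred, truth)
    d = dice(pred, truth)
    j = jaccard(pred, truth)
    nt = truth.voxel_count
    if nt == 0:
        vol_err = 0.0 if pred.voxel_count == 0 else float("inf")
    else:
        vol_err = (pred.voxel_count - nt) / nt
    hd = hausdorff(pred, truth)
    hd_mm = None
    if hd is not None and tuple(truth.spacing) != (1.0, 1.0, 1.0):
        hd_mm = hausdorff(pred, truth, spacing=truth.spacing)
    return EvalReport(dice=d, jaccard=j, volume_error=vol_err,
                      hausdorff=hd, hausdorff_mm=hd_mm)
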