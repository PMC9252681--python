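"""Per-modality denoising/normalization and linear multimodal fusion.

The pipeline preprocesses each channel with a cubic median filter and a
percentile-based contrast stretch to a common gray range [0, L-1], then
forms one scalar volume as a convex (weights sum to one) voxelwise
combination of the channels.  Stretching before fusion puts all modalities
on one scale so the weights are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import FilterRadiusError, ShapeMismatchError
from .io_volumes import ModalityStack, Volume3D

__all__ = [
    "StretchParams",
    "FusionWeights",
    "median_filter",
    "gray_stretch",
    "linear_fuse",
]


@dataclass
class StretchParams:
    """Contrast-stretch window and output quantization.

    ``low_percentile``/``high_percentile`` are fractions (0 = min, 1 = max);
    values outside the window clip to the window edges.  ``levels`` is the
    number of output gray levels L, so the output range is [0, L-1].
    """

    low_percentile: float = 0.0
    high_percentile: float = 1.0
    levels: int = 256

    def __post_init__(self) -> None:
        if not (0.0 <= self.low_percentile < 0.5):
            raise ValueError(f"low_percentile must be in [0, 0.5), got {self.low_percentile}")
        if not (0.5 < self.high_percentile <= 1.0):
            raise ValueError(f"high_percentile must be in (0.5, 1], got {self.high_percentile}")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")


@dataclass
class FusionWeights:
    """Nonnegative per-modality weights, normalized to sum to 1."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a nonempty 1D sequence")
        if np.any(w < 0):
            raise ValueError(f"weights must be nonnegative, got {self.weights}")
        total = w.sum()
        if total <= 0:
            raise ValueError("at least one weight must be positive")
        self.weights = tuple(float(x) for x in w / total)

    @classmethod
    def equal(cls, n: int) -> "FusionWeights":
        return cls(tuple(1.0 for _ in range(n)))


def median_filter(volume: Volume3D, radius: int = 1) -> Volume3D:
    """Cubic median filter of half-width ``radius`` with edge replication.

    ``radius`` 0 is the identity.  The (2r+1)^3 window must fit inside the
    volume extent.
    """
    if radius < 0:
        raise FilterRadiusError(f"radius must be >= 0, got {radius}")
    if radius == 0:
        return volume.with_data(volume.data.copy())
    size = 2 * radius + 1
    if any(size > dim for dim in volume.shape):
        raise FilterRadiusError(
            f"window {size}^3 exceeds volume extent {volume.shape}"
        )
    # mode="nearest" replicates edge voxels, matching the documented border rule
    out = ndimage.median_filter(volume.data, size=size, mode="nearest")
    return volume.with_data(out)


def gray_stretch(volume: Volume3D, params: StretchParams | None = None) -> Volume3D:
    """Affine contrast stretch of the percentile window onto [0, L-1].

    The low/high percentile values map to 0 and L-1; values outside the
    window are clipped.  A degenerate window (high == low, e.g. a constant
    volume) maps everything to 0 so blank channels stay usable.
    """
    params = params or StretchParams()
    data = volume.data.astype(np.float64)
    lo = float(np.quantile(data, params.low_percentile))
    hi = float(np.quantile(data, params.high_percentile))
    top = float(params.levels - 1)
    if hi <= lo:
        return volume.with_data(np.zeros_like(data))
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0) * top
    return volume.with_data(out)


def linear_fuse(stack: ModalityStack, weights: FusionWeights | None = None) -> Volume3D:
    """Voxelwise convex combination of the stack's channels.

    With no weights given every channel gets the same weight.  Inputs are
    expected to be on a common gray range already (see :func:`gray_stretch`).
    """
    if weights is None:
        weights = FusionWeights.equal(len(stack))
    if len(weights.weights) != len(stack):
        raise ShapeMismatchError(
            f"{len(weights.weights)} weights for {len(stack)} modalities"
        )
    fused = np.zeros(stack.shape, dtype=np.float64)
    for w, vol in zip(weights.weights, stack):
        fused += w * vol.data.astype(np.float64)
    return Volume3D(fused, stack.spacing, modality="fused")


def preprocess_stack(
    stack: ModalityStack,
    radius: int = 1,
    params: StretchParams | None = None,
) -> ModalityStack:
    """Median-filter then gray-stretch every channel (pipeline first stages)."""
    vols = [gray_stretch(median_filter(v, radius), params) for v in stack]
    return ModalityStack(vols, list(stack.names))
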