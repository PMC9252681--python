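"""Automatic threshold extraction of the bright (lesion-like) region.

The clustering stage deliberately under-segments: its brightest cluster
contains the lesion plus whatever bright tissue leaks in.  A global
automatic threshold — Otsu's between-class variance criterion, computed on
the compressed gray histogram — separates the target from its surround.
Foreground is strictly ``value > t``, which matters on quantized data where
whole populations sit exactly at the threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import HistogramError
from .ffcm import GrayHistogram
from .io_volumes import Volume3D
from .masks import Mask

__all__ = ["otsu_threshold", "apply_threshold", "largest_component", "Mask"]


def otsu_threshold(histogram: GrayHistogram) -> float:
    """Gray level t maximizing the between-class variance of {g <= t} vs {g > t}.

    Ties resolve to the lowest maximizing level.  Requires at least two
    distinct levels.  Invariant under uniform scaling of the counts.
    """
    if histogram.num_levels < 2:
        raise HistogramError("Otsu threshold needs >= 2 distinct gray levels")
    g = histogram.levels
    w = histogram.counts.astype(np.float64)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * g)
    mean_total = cum_m[-1] / total
    # candidates: every level except the last (both classes must be nonempty)
    w0 = cum_w[:-1] / total
    m0 = cum_m[:-1] / cum_w[:-1]
    w1 = 1.0 - w0
    m1 = (mean_total - w0 * m0) / w1
    sigma_b = w0 * w1 * (m0 - m1) ** 2
    return float(g[int(np.argmax(sigma_b))])  # argmax takes the first (lowest) tie


def apply_threshold(volume: Volume3D, t: float, within: Mask | None = None) -> Mask:
    """Binary mask of voxels with value strictly above ``t``.

    When ``within`` is given (typically the brightest-cluster mask) the
    result is intersected with it.
    """
    fg = volume.data > t
    if within is not None:
        if within.shape != volume.shape:
            raise HistogramError(
                f"within-mask shape {within.shape} != volume shape {volume.shape}"
            )
        fg = fg & within.data
    return Mask(fg, volume.spacing)


def largest_component(mask: Mask) -> Mask:
    """Keep only the largest 26-connected foreground component.

    Optional post-cleaning; an empty mask passes through unchanged.
    """
    if mask.voxel_count == 0:
        return mask
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask.data, structure=structure)
    if n <= 1:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return Mask(labels == int(np.argmax(sizes)), mask.spacing)
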