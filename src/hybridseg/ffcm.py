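"""Histogram-compressed fast fuzzy C-means (FFCM) clustering.

Standard fuzzy C-means minimizes

    J_f = sum_j sum_i mu_j(g_i)^r * (g_i - u_j)^2,   sum_j mu_j(g_i) = 1,

over all n = P*Q*W voxels.  Identical gray values receive identical
memberships, so every sum over voxels collapses to a sum over the distinct
gray levels weighted by their histogram counts h(g).  That compression is
what makes the method "fast": iterations run over a few hundred levels
instead of millions of voxels while J_f and the center trajectory are
unchanged (the voxelwise algorithm is kept in the test suite as the oracle
for this equivalence).

Updates are the unique stationary conditions of the Lagrangian:
membership inversely proportional to distance^(2/(r-1)), centers the
membership^r-weighted mean.  Centers are returned sorted ascending with
memberships permuted to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ClusterCountError, HistogramError
from .io_volumes import Volume3D
from .masks import Mask

__all__ = [
    "GrayHistogram",
    "FFCMModel",
    "LabelVolume",
    "build_histogram",
    "membership_matrix",
    "ffcm_objective",
    "ffcm_cluster",
    "classify_voxels",
    "brightest_cluster_mask",
]


@dataclass
class GrayHistogram:
    """Compressed image representation: distinct gray levels and their counts."""

    levels: np.ndarray
    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if levels.ndim != 1 or counts.shape != levels.shape:
            raise HistogramError("levels and counts must be matching 1D arrays")
        if levels.size == 0:
            raise HistogramError("histogram must have at least one level")
        if np.any(np.diff(levels) <= 0):
            raise HistogramError("levels must be strictly increasing")
        if np.any(counts < 1):
            raise HistogramError("every count must be >= 1")
        if int(counts.sum()) != int(self.total):
            raise HistogramError(
                f"counts sum to {int(counts.sum())}, expected total {self.total}"
            )
        self.levels = levels
        self.counts = counts
        self.total = int(self.total)

    @property
    def num_levels(self) -> int:
        return int(self.levels.size)


@dataclass
class FFCMModel:
    """Fitted FFCM state: sorted centers, per-level memberships, fit trace."""

    centers: np.ndarray
    memberships: np.ndarray  # shape (c, num_levels)
    levels: np.ndarray  # gray levels the membership columns refer to
    fuzzifier: float
    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False

    @property
    def num_clusters(self) -> int:
        return int(self.centers.size)


@dataclass
class LabelVolume:
    """Hard cluster assignment per voxel."""

    labels: np.ndarray
    num_clusters: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {labels.shape}")
        if labels.size and (labels.min() < 0 or labels.max() >= self.num_clusters):
            raise ValueError("labels outside [0, num_clusters)")
        self.labels = labels.astype(np.int32)


def build_histogram(volume: Volume3D) -> GrayHistogram:
    """Exact distinct-value histogram of a (quantized) volume."""
    data = volume.data
    if not np.all(np.isfinite(data)):
        raise HistogramError("volume contains non-finite values")
    levels, counts = np.unique(data.astype(np.float64), return_counts=True)
    return GrayHistogram(levels, counts, int(data.size))


def membership_matrix(levels: np.ndarray, centers: np.ndarray, r: float) -> np.ndarray:
    """Optimal memberships mu_j(g) for fixed centers.

    mu_j(g) = 1 / sum_k (|g-u_j| / |g-u_k|)^(2/(r-1)); a level equal to one
    or more centers splits its membership over exactly those centers.
    Columns sum to 1.
    """
    g = np.asarray(levels, dtype=np.float64)[None, :]
    u = np.asarray(centers, dtype=np.float64)[:, None]
    d2 = (g - u) ** 2
    zero = d2 == 0.0
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (r - 1.0))
    mu = np.empty_like(inv)
    hit = zero.any(axis=0)
    if np.any(hit):
        mu[:, hit] = zero[:, hit] / zero[:, hit].sum(axis=0)
    ok = ~hit
    mu[:, ok] = inv[:, ok] / inv[:, ok].sum(axis=0)
    return mu


def ffcm_objective(
    histogram: GrayHistogram, centers: np.ndarray, memberships: np.ndarray, r: float
) -> float:
    """J_f evaluated with histogram weights (equal to the voxelwise sum)."""
    d2 = (histogram.levels[None, :] - np.asarray(centers, dtype=np.float64)[:, None]) ** 2
    return float((histogram.counts[None, :] * memberships**r * d2).sum())


def _init_centers(levels: np.ndarray, c: int, seed: int, jitter: float) -> np.ndarray:
    """Deterministic spread over the distinct-level support.

    Centers sit at evenly spaced quantiles of the sorted distinct levels
    (not count-weighted: a dominant background mode would otherwise collapse
    several initial centers onto one point, and coincident centers receive
    identical updates forever).  ``jitter`` > 0 adds a small seeded
    perturbation.
    """
    n = levels.size
    idx = np.floor((np.arange(c) + 0.5) / c * n).astype(int)
    idx = np.clip(idx, 0, n - 1)
    # enforce distinct indices when c is close to the number of levels
    for i in range(1, c):
        if idx[i] <= idx[i - 1]:
            idx[i] = idx[i - 1] + 1
    centers = levels[np.clip(idx, 0, n - 1)].astype(np.float64)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        span = float(levels[-1] - levels[0]) or 1.0
        centers = centers + rng.normal(0.0, jitter * span / c, size=c)
    return centers


def ffcm_cluster(
    histogram: GrayHistogram,
    c: int = 4,
    r: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 200,
    seed: int = 0,
    init_centers: np.ndarray | None = None,
    jitter: float = 0.0,
) -> FFCMModel:
    """Alternating-update FFCM on a gray histogram.

    Stops when the largest center shift drops below ``tol`` or after
    ``max_iter`` iterations (then ``converged`` is False; not an error).
    ``init_centers`` overrides the default quantile initialization — the
    oracle-equivalence tests use it to share one start between the
    histogram-weighted and voxelwise algorithms.
    """
    if c < 1:
        raise ClusterCountError(f"cluster count must be >= 1, got {c}")
    if c > histogram.num_levels:
        raise ClusterCountError(
            f"c={c} exceeds the {histogram.num_levels} distinct gray levels"
        )
    if r <= 1.0:
        raise ValueError(f"fuzzifier r must be > 1, got {r}")
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")

    g = histogram.levels
    h = histogram.counts.astype(np.float64)
    if init_centers is not None:
        centers = np.asarray(init_centers, dtype=np.float64).copy()
        if centers.shape != (c,):
            raise ValueError(f"init_centers must have shape ({c},)")
    else:
        centers = _init_centers(g, c, seed, jitter)

    trace: list[float] = []
    converged = False
    mu = membership_matrix(g, centers, r)
    iterations = 0
    for iterations in range(1, max_iter + 1):
        weights = h[None, :] * mu**r
        denom = weights.sum(axis=1)
        new_centers = np.where(denom > 0, (weights * g[None, :]).sum(axis=1) / np.where(denom > 0, denom, 1.0), centers)
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        mu = membership_matrix(g, centers, r)
        trace.append(ffcm_objective(histogram, centers, mu, r))
        if shift < tol:
            converged = True
            break

    order = np.argsort(centers, kind="stable")
    return FFCMModel(
        centers=centers[order],
        memberships=mu[order, :],
        levels=g.copy(),
        fuzzifier=float(r),
        objective_trace=trace,
        iterations=iterations,
        converged=converged,
    )


def _level_indices(values: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Index of the nearest histogram level for each value."""
    idx = np.searchsorted(levels, values.ravel())
    idx = np.clip(idx, 0, levels.size - 1)
    left = np.clip(idx - 1, 0, levels.size - 1)
    use_left = np.abs(values.ravel() - levels[left]) <= np.abs(levels[idx] - values.ravel())
    idx = np.where(use_left, left, idx)
    return idx.reshape(values.shape)


def classify_voxels(volume: Volume3D, model: FFCMModel) -> LabelVolume:
    """Hard-assign each voxel to its maximal-membership cluster.

    Values not present in the histogram snap to the nearest level.  Ties go
    to the cluster with the higher center (centers are sorted, so the higher
    index).
    """
    c = model.num_clusters
    # argmax on the reversed rows finds the LAST maximal row => higher center
    per_level = (c - 1) - np.argmax(model.memberships[::-1, :], axis=0)
    idx = _level_indices(volume.data.astype(np.float64), model.levels)
    return LabelVolume(per_level[idx], c)


def brightest_cluster_mask(label_volume: LabelVolume, model: FFCMModel,
                           spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> Mask:
    """Mask of voxels in the cluster with the largest center (the bright,
    lesion-like class the downstream threshold refines)."""
    brightest = int(np.argmax(model.centers))
    return Mask(label_volume.labels == brightest, spacing)
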