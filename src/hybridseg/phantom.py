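"""Seeded synthetic multimodal MRI phantoms with ground truth.

The phantom is deliberately simple: piecewise-constant tissue classes
(air background, a gray-matter-like brain ellipsoid, a white-matter-like
core) plus ellipsoidal lesions, rendered per modality and corrupted by
additive Gaussian or Rician noise.  Lesion signal profiles are qualitative,
following the classic MR appearance of intracranial melanocytic lesions:

* ``melanotic``  - melanin shortens T1 and T2, so the lesion is brighter
  than brain on the T1-like channel and darker on the T2-like channel;
* ``amelanotic`` - the reverse (low-or-equally-low T1, high-or-equally-high
  T2);
* ``mixed``      - two sub-regions inside one lesion, one of each kind.

Absolute intensities are free parameters on a [0, 255] scale (so phantoms
can bypass the contrast stretch in unit tests); the defaults below are the
package's documented choice.  An optional edema halo adds a FLAIR-bright
rim.  Everything is reproducible from the spec's seed, and the ground-truth
mask never depends on the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_volumes import ModalityStack, Volume3D, make_stack
from .masks import Mask

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "generate_phantom",
    "profile_contrast_check",
    "default_melanotic_spec",
    "PROFILE_MEANS",
    "TISSUE_MEANS",
    "MODALITIES",
]

MODALITIES: tuple[str, ...] = ("T1WI", "T2WI", "FLAIR")

# per-modality class means on [0, 255], in MODALITIES order
TISSUE_MEANS: dict[str, tuple[float, ...]] = {
    "background": (5.0, 5.0, 5.0),
    "gray": (110.0, 140.0, 130.0),
    "white": (150.0, 100.0, 110.0),
}

PROFILE_MEANS: dict[str, tuple[float, ...]] = {
    "melanotic": (240.0, 40.0, 240.0),
    "amelanotic": (60.0, 230.0, 210.0),
}

EDEMA_MEANS: tuple[float, ...] = (90.0, 190.0, 200.0)

PROFILES = ("melanotic", "amelanotic", "mixed")


@dataclass
class LesionSpec:
    """One ellipsoidal lesion.

    ``center`` in voxel coordinates, ``semi_axes`` in voxels (each >= 1),
    ``profile`` one of ``melanotic``/``amelanotic``/``mixed``;
    ``rim_edema`` > 0 adds a halo of that width with intermediate,
    FLAIR-bright intensity (the halo is not part of the ground truth).
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    profile: str = "melanotic"
    rim_edema: float = 0.0

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; choose from {PROFILES}")
        if any(a < 1 for a in self.semi_axes):
            raise ValueError(f"semi_axes must each be >= 1, got {self.semi_axes}")
        if self.rim_edema < 0:
            raise ValueError("rim_edema must be >= 0")


@dataclass
class PhantomSpec:
    """Geometry, per-class signal means and noise description."""

    shape: tuple[int, int, int] = (64, 64, 64)
    tissue_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(TISSUE_MEANS)
    )
    lesions: list[LesionSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"
    seed: int = 0
    modalities: tuple[str, ...] = MODALITIES
    profile_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(PROFILE_MEANS)
    )

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        n = len(self.modalities)
        for name, means in {**self.tissue_means, **self.profile_means}.items():
            if len(means) != n:
                raise ValueError(f"{name!r} means must have {n} channels")
            if any(not (0 <= m <= 255) for m in means):
                raise ValueError(f"{name!r} means must lie in [0, 255]")


def _ellipsoid(shape: tuple[int, int, int], center: Sequence[float],
               semi_axes: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _check_inside(shape, lesion: LesionSpec) -> None:
    for c, a, s in zip(lesion.center, lesion.semi_axes, shape):
        if c - a - lesion.rim_edema < 0 or c + a + lesion.rim_edema > s - 1:
            raise ValueError(
                f"lesion at {lesion.center} with semi-axes {lesion.semi_axes} "
                f"(edema {lesion.rim_edema}) extends outside grid {shape}"
            )


def generate_phantom(spec: PhantomSpec) -> tuple[ModalityStack, Mask]:
    """Render the phantom; returns (multimodal stack, ground-truth mask).

    With ``noise_sigma`` 0 every voxel equals its class mean exactly.  The
    same spec (including seed) always reproduces bit-identical volumes.
    """
    shape = tuple(int(s) for s in spec.shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    brain = _ellipsoid(shape, center, tuple(0.42 * s for s in shape))
    core = _ellipsoid(shape, center, tuple(0.26 * s for s in shape))

    n_chan = len(spec.modalities)
    channels = [np.full(shape, spec.tissue_means["background"][m], dtype=np.float64)
                for m in range(n_chan)]
    for m in range(n_chan):
        channels[m][brain] = spec.tissue_means["gray"][m]
        channels[m][core] = spec.tissue_means["white"][m]

    truth = np.zeros(shape, dtype=bool)
    for lesion in spec.lesions:
        _check_inside(shape, lesion)
        body = _ellipsoid(shape, lesion.center, lesion.semi_axes)
        if lesion.rim_edema > 0:
            halo = _ellipsoid(
                shape, lesion.center,
                tuple(a + lesion.rim_edema for a in lesion.semi_axes),
            ) & ~body
            for m in range(n_chan):
                channels[m][halo] = EDEMA_MEANS[m]
        if lesion.profile == "mixed":
            axis0 = np.arange(shape[0])[:, None, None]
            upper = body & (axis0 >= lesion.center[0])
            lower = body & (axis0 < lesion.center[0])
            for m in range(n_chan):
                channels[m][upper] = spec.profile_means["melanotic"][m]
                channels[m][lower] = spec.profile_means["amelanotic"][m]
        else:
            means = spec.profile_means[lesion.profile]
            for m in range(n_chan):
                channels[m][body] = means[m]
        truth |= body

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        for m in range(n_chan):
            if spec.noise_model == "gaussian":
                channels[m] += rng.normal(0.0, spec.noise_sigma, size=shape)
            else:  # rician: magnitude of a complex signal with Gaussian parts
                n1 = rng.normal(0.0, spec.noise_sigma, size=shape)
                n2 = rng.normal(0.0, spec.noise_sigma, size=shape)
                channels[m] = np.sqrt((channels[m] + n1) ** 2 + n2**2)

    volumes = [Volume3D(ch, modality=name) for ch, name in zip(channels, spec.modalities)]
    return make_stack(volumes), Mask(truth)


def default_melanotic_spec(
    shape: tuple[int, int, int] = (64, 64, 64),
    noise_sigma: float = 5.0,
    seed: int = 42,
    profile: str = "melanotic",
) -> PhantomSpec:
    """The documented reference phantom: one off-center lesion of semi-axes
    scaled to the grid (10, 8, 7 voxels at 64^3)."""
    scale = shape[0] / 64.0
    lesion = LesionSpec(
        center=(40.0 * scale, 28.0 * scale, 32.0 * scale),
        semi_axes=(10.0 * scale, 8.0 * scale, 7.0 * scale),
        profile=profile,
    )
    return PhantomSpec(shape=shape, lesions=[lesion],
                       noise_sigma=noise_sigma, seed=seed)


def profile_contrast_check(stack: ModalityStack, truth: Mask, profile: str) -> dict:
    """Verify the per-channel lesion-vs-brain intensity orderings.

    Compares the mean lesion intensity against the mean of a 3-voxel shell
    around the lesion (local brain surround).  Channel roles follow stack
    order: first = T1-like, second = T2-like; further channels are reported
    but not constrained.  Returns a report dict with an overall ``ok``.
    """
    from scipy import ndimage

    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    shell = ndimage.binary_dilation(truth.data, iterations=3) & ~truth.data
    report: dict = {"profile": profile, "channels": [], "ok": True}
    expectations = {"melanotic": (">", "<"), "amelanotic": ("<", ">")}
    for idx, (vol, name) in enumerate(zip(stack, stack.names)):
        lesion_mean = float(vol.data[truth.data].mean())
        brain_mean = float(vol.data[shell].mean())
        entry = {"name": name, "lesion_mean": lesion_mean, "surround_mean": brain_mean}
        if profile in expectations and idx < 2:
            want = expectations[profile][idx]
            ok = lesion_mean > brain_mean if want == ">" else lesion_mean < brain_mean
            entry["expected"] = f"lesion {want} surround"
            entry["ok"] = bool(ok)
            report["ok"] &= bool(ok)
        report["channels"].append(entry)
    return report
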