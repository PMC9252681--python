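"""End-to-end orchestration of the hybrid segmentation flow.

Stage order is fixed: median filter -> gray stretch -> linear fusion ->
FFCM clustering -> automatic threshold -> hybrid level set.  Every tunable
lives in :class:`PipelineConfig`, which round-trips through YAML; identical
input, config and seed give bit-identical outputs.

Threshold strategies
--------------------
``otsu_top2`` (default)
    Otsu on the fused-image histogram restricted to the union of the two
    brightest FFCM clusters.  That population is bimodal (target plus its
    bright surround), which is the regime Otsu's between-class-variance
    criterion is built for.
``otsu_within``
    Otsu restricted to the brightest cluster alone.  When that cluster is
    already pure target the histogram is (near-)unimodal and the criterion
    splits the target itself; a degenerate (single-level) histogram falls
    back to the midpoint of the two brightest cluster centers.
``otsu_global``
    Otsu on the full fused histogram, intersected with the brightest
    cluster.

In every strategy the threshold doubles as the level-set gray lower limit
mu (rescaled to [0, 1]) unless ``auto_mu`` is disabled.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from ._version import __version__
from .auto_threshold import apply_threshold, largest_component, otsu_threshold
from .errors import ConfigError, HistogramError, HybridsegError, StageError
from .ffcm import (
    GrayHistogram,
    brightest_cluster_mask,
    build_histogram,
    classify_voxels,
    ffcm_cluster,
)
from .hybrid_levelset import LevelSetParams, run_levelset
from .io_volumes import ModalityStack, Volume3D, write_volume
from .masks import Mask
from .preprocess_fusion import (
    FusionWeights,
    StretchParams,
    gray_stretch,
    linear_fuse,
    median_filter,
)

__all__ = [
    "FFCMConfig",
    "PipelineConfig",
    "RunReport",
    "default_config",
    "load_config",
    "save_config",
    "run_pipeline",
]

THRESHOLD_STRATEGIES = ("otsu_top2", "otsu_within", "otsu_global")


@dataclass
class FFCMConfig:
    """Clustering stage knobs: cluster count c, fuzzifier r, stopping rule."""

    c: int = 4
    r: float = 2.0
    tol: float = 1e-5
    max_iter: int = 200
    seed: int = 0


@dataclass
class PipelineConfig:
    median_radius: int = 1
    stretch: StretchParams = field(default_factory=StretchParams)
    fusion_weights: list[float] | None = None  # None = equal weights
    ffcm: FFCMConfig = field(default_factory=FFCMConfig)
    threshold_strategy: str = "otsu_top2"
    levelset: LevelSetParams = field(default_factory=LevelSetParams)
    auto_mu: bool = True
    keep_largest_component: bool = False
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return {
            "median_radius": self.median_radius,
            "stretch": dataclasses.asdict(self.stretch),
            "fusion_weights": list(self.fusion_weights) if self.fusion_weights else None,
            "ffcm": dataclasses.asdict(self.ffcm),
            "threshold_strategy": self.threshold_strategy,
            "levelset": dataclasses.asdict(self.levelset),
            "auto_mu": self.auto_mu,
            "keep_largest_component": self.keep_largest_component,
            "output_dir": self.output_dir,
        }


@dataclass
class RunReport:
    """Auditable record of one pipeline run (stages in execution order)."""

    stages: list[dict] = field(default_factory=list)
    threshold: float | None = None
    config: dict = field(default_factory=dict)
    version: str = __version__
    seed: int = 0

    def add_stage(self, name: str, seconds: float, **details: Any) -> None:
        self.stages.append({"name": name, "seconds": seconds, **details})

    @property
    def stage_names(self) -> list[str]:
        return [s["name"] for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "threshold": self.threshold,
            "config": self.config,
            "version": self.version,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


# ---------------------------------------------------------------------------
# config validation / (de)serialization

def default_config() -> PipelineConfig:
    return PipelineConfig()


def _build_section(cls, section: dict, prefix: str, problems: list[str]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    for key in sorted(unknown):
        problems.append(f"{prefix}{key}: unknown key")
    kwargs = {k: v for k, v in section.items() if k in known}
    try:
        return cls(**kwargs)
    except (ValueError, ConfigError) as exc:
        problems.append(f"{prefix.rstrip('.') or 'config'}: {exc}")
        return cls()


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a validated config; every problem is reported, field by field."""
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    problems: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key in sorted(set(raw) - known):
        problems.append(f"{key}: unknown key")

    kwargs: dict[str, Any] = {}
    for section_name, cls in (("stretch", StretchParams), ("ffcm", FFCMConfig),
                              ("levelset", LevelSetParams)):
        if section_name in raw:
            section = raw[section_name]
            if not isinstance(section, dict):
                problems.append(f"{section_name}: must be a mapping")
            else:
                kwargs[section_name] = _build_section(
                    cls, section, f"{section_name}.", problems
                )
    for key in ("median_radius", "fusion_weights", "threshold_strategy",
                "auto_mu", "keep_largest_component", "output_dir"):
        if key in raw:
            kwargs[key] = raw[key]

    if "ffcm" in kwargs and kwargs["ffcm"].r <= 1.0:
        problems.append(
            f"ffcm.r: fuzzifier must be a constant > 1, got {kwargs['ffcm'].r}"
        )
    if kwargs.get("threshold_strategy", "otsu_top2") not in THRESHOLD_STRATEGIES:
        problems.append(
            f"threshold_strategy: {kwargs['threshold_strategy']!r} not in "
            f"{THRESHOLD_STRATEGIES}"
        )
    if kwargs.get("median_radius", 1) < 0:
        problems.append("median_radius: must be >= 0")
    fw = kwargs.get("fusion_weights")
    if fw is not None:
        try:
            FusionWeights(tuple(fw))
        except (TypeError, ValueError) as exc:
            problems.append(f"fusion_weights: {exc}")

    if problems:
        raise ConfigError(problems)
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError([f"malformed config file: {exc}"]) from exc
    return config_from_dict(raw or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# the pipeline

def _stage(report: RunReport, name: str, fn, **details):
    start = time.perf_counter()
    try:
        result = fn()
    except HybridsegError as exc:
        raise StageError(name, exc) from exc
    report.add_stage(name, time.perf_counter() - start, **details)
    return result


def _threshold_value(cfg: PipelineConfig, quantized: Volume3D,
                     histogram: GrayHistogram, labels, model) -> float:
    """Resolve the automatic threshold according to the configured strategy."""
    c = model.num_clusters
    centers = model.centers

    def midpoint_fallback() -> float:
        if c >= 2:
            return float(0.5 * (centers[-1] + centers[-2]))
        return float(histogram.levels[0] - 1.0)

    if cfg.threshold_strategy == "otsu_global":
        return otsu_threshold(histogram)

    if cfg.threshold_strategy == "otsu_within":
        region = labels.labels == c - 1
    else:  # otsu_top2
        region = labels.labels >= max(c - 2, 0)
    values = quantized.data[region]
    if values.size == 0:
        return midpoint_fallback()
    levels, counts = np.unique(values, return_counts=True)
    if levels.size < 2:
        return midpoint_fallback()
    return otsu_threshold(GrayHistogram(levels, counts, int(values.size)))


def run_pipeline(stack: ModalityStack, cfg: PipelineConfig | None = None,
                 save_intermediates: bool = False) -> tuple[Mask, RunReport]:
    """Segment a multimodal stack; returns the final mask and the run report.

    Raises :class:`StageError` naming the failing stage; an empty threshold
    mask aborts (there is nothing for the level set to refine).
    """
    cfg = cfg or default_config()
    report = RunReport(config=cfg.to_dict(), seed=cfg.ffcm.seed)
    out_dir: Path | None = None
    if save_intermediates and cfg.output_dir:
        out_dir = Path(cfg.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    filtered = _stage(
        report, "median_filter",
        lambda: [median_filter(v, cfg.median_radius) for v in stack],
        radius=cfg.median_radius,
    )
    stretched = _stage(
        report, "gray_stretch",
        lambda: [gray_stretch(v, cfg.stretch) for v in filtered],
        levels=cfg.stretch.levels,
    )
    pre_stack = ModalityStack(stretched, list(stack.names))
    weights = (FusionWeights(tuple(cfg.fusion_weights))
               if cfg.fusion_weights else FusionWeights.equal(len(stack)))
    fused = _stage(report, "linear_fusion",
                   lambda: linear_fuse(pre_stack, weights),
                   weights=list(weights.weights))

    quantized = fused.with_data(np.rint(fused.data))
    histogram = build_histogram(quantized)
    model = _stage(
        report, "ffcm",
        lambda: ffcm_cluster(histogram, c=cfg.ffcm.c, r=cfg.ffcm.r,
                             tol=cfg.ffcm.tol, max_iter=cfg.ffcm.max_iter,
                             seed=cfg.ffcm.seed),
    )
    report.stages[-1].update(
        iterations=model.iterations, converged=model.converged,
        centers=[float(x) for x in model.centers],
        objective_trace=[float(x) for x in model.objective_trace],
    )
    labels = classify_voxels(quantized, model)
    bright = brightest_cluster_mask(labels, model, stack.spacing)

    def threshold_stage() -> Mask:
        t = _threshold_value(cfg, quantized, histogram, labels, model)
        report.threshold = float(t)
        mask = apply_threshold(quantized, t, within=bright)
        if cfg.keep_largest_component:
            mask = largest_component(mask)
        if mask.voxel_count == 0:
            raise HistogramError(
                "threshold produced an empty mask; nothing for the level set to refine"
            )
        return mask

    thresholded = _stage(report, "auto_threshold", threshold_stage,
                         strategy=cfg.threshold_strategy)
    report.stages[-1]["threshold"] = report.threshold
    report.stages[-1]["voxel_count"] = thresholded.voxel_count

    top = float(cfg.stretch.levels - 1)
    U = Volume3D(np.clip(fused.data / top, 0.0, 1.0), stack.spacing, "fused01")
    ls_params = dataclasses.replace(cfg.levelset)
    if cfg.auto_mu and report.threshold is not None:
        ls_params.mu = float(report.threshold) / top

    def levelset_stage():
        return run_levelset(U, thresholded, ls_params, full_output=True)

    final, state, converged = _stage(report, "hybrid_levelset", levelset_stage,
                                     mu=ls_params.mu)
    report.stages[-1].update(
        iterations=state.iteration, converged=bool(converged),
        front_volume_trace=state.front_volume_trace,
        final_voxel_count=final.voxel_count,
    )

    if out_dir is not None:
        write_volume(fused, out_dir / "fused.nii.gz")
        write_volume(Volume3D(labels.labels.astype(np.float32), stack.spacing,
                              "labels"), out_dir / "ffcm_labels.nii.gz")
        write_volume(Volume3D(thresholded.data.astype(np.float32), stack.spacing,
                              "threshold_mask"), out_dir / "threshold_mask.nii.gz")
        write_volume(Volume3D(final.data.astype(np.float32), stack.spacing,
                              "final_mask"), out_dir / "final_mask.nii.gz")
        report.to_json(out_dir / "report.json")

    return final, report
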