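"""End-to-end segmentation pipelines (fuzzy connectedness and RRG).

``run_fc_pipeline`` chains the full method: optional CT windowing ->
seed-cube parameter estimation -> seed replacement -> affinity lookup
table -> connectivity propagation -> histogram -> adaptive (or manual)
threshold -> mask + volumetrics, and records a provenance dictionary
sufficient to re-run the exact configuration.  ``run_rrg_pipeline`` runs
the region-growing comparator on the same windowed scene.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from . import __version__
from .adaptive_threshold import (
    DEFAULT_BINS,
    DEFAULT_MAX_VOLUME_ML,
    DEFAULT_MIN_PEAK_RISE,
    DEFAULT_SMOOTH_WINDOW,
    ThresholdResult,
    apply_threshold,
    histogram,
    suggest_threshold,
)
from .affinity import AffinityParams, build_lut
from .connectedness import ConnectivityScene, compute_connectivity
from .evaluation import VolumeReport, mask_volume
from .rrg_baseline import MIN_JUMP_RATIO, RRGTrace, rrg_segment
from .scene_io import Scene, SegmentationMask, window_to_byte, write_scene
from .seed_params import SeedSpec, estimate_params, replace_seed_value

__all__ = ["PipelineConfig", "FCResult", "RRGResult", "run_fc_pipeline", "run_rrg_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a segmentation run."""

    seed: Tuple[int, int, int] = (0, 0, 0)
    window: Optional[Tuple[float, float]] = None  # HU window; None = already 8-bit
    cube_edge: int = 20
    bins: int = DEFAULT_BINS
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    max_volume_ml: float = DEFAULT_MAX_VOLUME_ML
    min_peak_rise: float = DEFAULT_MIN_PEAK_RISE
    manual_threshold: Optional[float] = None
    use_lut: bool = True
    # RRG-only knobs
    theta_end: Optional[int] = None
    rrg_volume_cap_ml: Optional[float] = None
    rrg_min_jump_ratio: float = MIN_JUMP_RATIO


@dataclass
class FCResult:
    mask: SegmentationMask
    connectivity: ConnectivityScene
    threshold: ThresholdResult
    params: AffinityParams
    volume: VolumeReport
    provenance: dict


@dataclass
class RRGResult:
    mask: SegmentationMask
    trace: RRGTrace
    volume: VolumeReport
    provenance: dict


def _stage(name):
    logger.info("stage: %s", name)
    return time.perf_counter()


def _prepare_scene(scene: Scene, config: PipelineConfig) -> Scene:
    if config.window is not None:
        lo, hi = config.window
        return window_to_byte(scene, lo, hi)
    return scene


def run_fc_pipeline(scene: Scene, config: PipelineConfig) -> FCResult:
    """Run the adaptive-threshold fuzzy-connectedness segmentation."""
    try:
        stage = "window"
        work = _prepare_scene(scene, config)
        stage = "estimate_params"
        seed_spec = SeedSpec(tuple(config.seed), cube_edge=config.cube_edge)
        params = estimate_params(work, seed_spec)
        stage = "replace_seed_value"
        work = replace_seed_value(work, seed_spec, params)
        stage = "connectivity"
        if config.use_lut:
            cs = compute_connectivity(work, seed_spec.index, lut=build_lut(params))
        else:
            cs = compute_connectivity(work, seed_spec.index, params=params)
        stage = "threshold"
        hist = histogram(cs, bins=config.bins)
        if config.manual_threshold is not None:
            from .adaptive_threshold import volume_above

            t = float(config.manual_threshold)
            threshold = ThresholdResult(
                T=t, EP=t, ep_is_peak=False, volume_at_T_ml=volume_above(t, hist)
            )
        else:
            threshold = suggest_threshold(
                hist,
                max_volume_ml=config.max_volume_ml,
                smooth_window=config.smooth_window,
                min_peak_rise=config.min_peak_rise,
            )
        stage = "apply_threshold"
        mask = apply_threshold(cs, threshold.T)
        volume = mask_volume(mask)
    except Exception as exc:
        raise RuntimeError(f"FC pipeline failed at stage {stage!r}: {exc}") from exc
    provenance = {
        "method": "fuzzy_connectedness",
        "version": __version__,
        "config": asdict(config),
        "m": params.m,
        "s": params.s,
        "T": threshold.T,
        "EP": threshold.EP,
        "ep_is_peak": threshold.ep_is_peak,
        "voxel_count": volume.voxel_count,
        "volume_ml": volume.volume_ml,
    }
    return FCResult(mask, cs, threshold, params, volume, provenance)


def run_rrg_pipeline(scene: Scene, config: PipelineConfig) -> RRGResult:
    """Run the refined region-growing comparator."""
    if config.theta_end is None:
        raise ValueError("RRG requires theta_end in the configuration")
    try:
        stage = "window"
        work = _prepare_scene(scene, config)
        stage = "rrg"
        mask, trace = rrg_segment(
            work,
            tuple(config.seed),
            config.theta_end,
            volume_cap_ml=config.rrg_volume_cap_ml,
            min_jump_ratio=config.rrg_min_jump_ratio,
        )
        volume = mask_volume(mask)
    except Exception as exc:
        raise RuntimeError(f"RRG pipeline failed at stage {stage!r}: {exc}") from exc
    provenance = {
        "method": "refined_region_growing",
        "version": __version__,
        "config": asdict(config),
        "theta_beg": int(trace.thetas[0]),
        "theta_opt": int(trace.theta_opt),
        "voxel_count": volume.voxel_count,
        "volume_ml": volume.volume_ml,
    }
    return RRGResult(mask, trace, volume, provenance)


def write_fc_artifacts(result: FCResult, outdir: Path, fmt: str = "nifti") -> None:
    """Persist mask, connectivity scene and provenance under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"nifti": ".nii.gz", "metaimage": ".mha"}[fmt]
    write_scene(result.mask, outdir / f"mask{ext}", format=fmt)
    cs_scene = Scene(result.connectivity.values.astype(np.float32), result.connectivity.spacing)
    write_scene(cs_scene, outdir / f"connectivity{ext}", format=fmt)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)


def write_rrg_artifacts(result: RRGResult, outdir: Path, fmt: str = "nifti") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"nifti": ".nii.gz", "metaimage": ".mha"}[fmt]
    write_scene(result.mask, outdir / f"mask{ext}", format=fmt)
    result.trace.to_csv(outdir / "rrg_trace.csv")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)
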