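"""End-to-end orchestration: masks → features → training → SVM → map.

``run_pipeline`` executes the full chain on one scene pair and returns the
six-category change map together with a :class:`RunManifest` capturing the
configuration snapshot, input checksums, per-stage timings and the filter
report, so a run is reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .classify import TrainedModel, grid_search, predict_map, train
from .config import PipelineConfig
from .features import FeatureStack, kt_coefficients, mkt_stack, swir_difference
from .masking import MaskSet, combine_masks
from .postprocess import compose_final, morphological_clean, plurality_label, segment
from .raster_io import ChangeMap, ScenePair
from .training import FilterReport, TrainingSet, consensus_filter, extract_training
from .validation import AccuracyReport, assess, stratified_sample

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict[str, Any]
    input_checksums: dict[str, str]
    seed: int
    stage_timings: dict[str, float] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    filter_summary: dict[str, Any] | None = None
    output_paths: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    change_map: ChangeMap
    manifest: RunManifest
    masks: MaskSet
    stack: FeatureStack
    training: TrainingSet
    filtered: TrainingSet
    filter_report: FilterReport | None
    model: TrainedModel
    pixel_labels: np.ndarray  # post-cleaning per-pixel labels


def run_pipeline(
    pair: ScenePair, cfg: PipelineConfig, sensor: str = "TM"
) -> PipelineResult:
    """Run every stage on a scene pair; any stage error aborts with context."""
    manifest = RunManifest(
        config=cfg.to_dict(),
        input_checksums={
            "early": _checksum(pair.early.band_stack()),
            "late": _checksum(pair.late.band_stack()),
        },
        seed=cfg.rng_seed,
    )

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest.stage_timings[name] = round(time.perf_counter() - t0, 3)
        return out

    masks = stage("mask", lambda: combine_masks(pair, cfg))
    manifest.stage_counts["valid_pixels"] = int(masks.valid.sum())
    coeffs = kt_coefficients(sensor)
    stack = stage("features", lambda: mkt_stack(pair, coeffs))
    diff = stage("difference", lambda: swir_difference(pair, cfg.swir_band))
    training = stage("extract", lambda: extract_training(diff, masks, stack, cfg))
    manifest.stage_counts["training_samples"] = len(training)

    filter_report: FilterReport | None = None
    if cfg.filter_enabled:
        filtered, filter_report = stage("filter", lambda: consensus_filter(training, cfg))
        manifest.stage_counts["samples_removed"] = len(filter_report.removed_ids)
        manifest.filter_summary = {
            "removal_fraction": filter_report.removal_fraction,
            "n_original": filter_report.n_original,
            "fold_count": filter_report.fold_count,
            "train_fraction_used": filter_report.train_fraction_used,
        }
    else:
        filtered = training

    params = stage("grid_search", lambda: grid_search(filtered, cfg))
    model = stage("train", lambda: train(filtered, params, cfg))
    labels = stage("predict", lambda: predict_map(model, stack, masks))
    labels = stage("clean", lambda: morphological_clean(labels, cfg))
    seg = stage("segment", lambda: segment(pair, masks, cfg))
    manifest.stage_counts["segments"] = seg.n_segments
    seg_labels = stage("plurality", lambda: plurality_label(seg, labels))
    cmap = stage(
        "compose",
        lambda: compose_final(seg, seg_labels, masks, pair.nodata_mask, pair.grid),
    )
    manifest.stage_counts["polygons"] = len(cmap.polygons)
    return PipelineResult(
        change_map=cmap,
        manifest=manifest,
        masks=masks,
        stack=stack,
        training=training,
        filtered=filtered,
        filter_report=filter_report,
        model=model,
        pixel_labels=labels,
    )


def run_validation(cmap: ChangeMap, truth, cfg: PipelineConfig) -> AccuracyReport:
    """Stratified polygon sample of the map assessed against reference truth."""
    if truth is None:
        raise ValueError("validation requires reference truth")
    sample = stratified_sample(cmap, cfg)
    return assess(sample, cmap, truth)


def corrupted_mask_replicates(
    n_replicates: int = 10,
    base_seed: int = 100,
    size: int = 128,
    sensor: str = "TM",
) -> list[dict[str, float]]:
    """Seeded paired runs with deliberately corrupted forest masks.

    Each replicate generates a fresh synthetic pair, corrupts the forest
    mask by injecting the agricultural confuser class into the analysis
    region (emulating forest-mask commission error), and classifies with
    raw and with filtered training; the returned dicts carry both false-
    positive rates.  Scene and analysis sizes are scaled to the replicate
    count so the whole sweep stays fast.
    """
    from .masking import combine_mask_planes
    from .synthetic_scene import AGRICULTURE, SceneSpec, generate_scene_pair

    results = []
    for i in range(n_replicates):
        spec = SceneSpec(width=size, height=size, seed=base_seed + i, frac_cloud=0.0)
        pair, truth = generate_scene_pair(spec)
        cfg = PipelineConfig(
            window_size=size,
            rng_seed=base_seed + i,
            min_tail_count=10,
            svm_c_exp=(1, 5, 2),
            svm_gamma_exp=(-5, -1, 2),
            grid_search_max_samples=500,
            max_training_samples=2500,
        )
        masks = combine_masks(pair, cfg)
        corrupted = masks.forest_early | (truth.condition == AGRICULTURE)
        masks = combine_mask_planes(
            masks.cloud_early, masks.cloud_late,
            masks.shadow_early, masks.shadow_late,
            masks.water_early, masks.water_late,
            corrupted, masks.forest_late, pair.nodata_mask,
        )
        results.append(compare_filter_effect(pair, masks, truth.change, cfg, sensor))
    return results


def compare_filter_effect(
    pair: ScenePair,
    masks: MaskSet,
    truth_change: np.ndarray,
    cfg: PipelineConfig,
    sensor: str = "TM",
) -> dict[str, float]:
    """Paired run: classify once with raw and once with filtered training.

    Returns the pixel-level disturbance false-positive rates of both runs
    over the valid region (false positive = predicted disturbed where the
    reference says the pixel did not lose forest), plus the filter's
    removal fraction.  Used to check that consensus filtering does not
    increase — and typically reduces — commission error when the masks
    leak non-forest into the analysis region.
    """
    from .synthetic_scene import CHANGE_DISTURBED
    from .training import DISTURBED as DISTURBED_LABEL

    coeffs = kt_coefficients(sensor)
    stack = mkt_stack(pair, coeffs)
    diff = swir_difference(pair, cfg.swir_band)
    raw = extract_training(diff, masks, stack, cfg)
    filtered, report = consensus_filter(raw, cfg)
    out: dict[str, float] = {"removal_fraction": report.removal_fraction}

    truly_disturbed = truth_change == CHANGE_DISTURBED
    for name, ts in (("unfiltered", raw), ("filtered", filtered)):
        params = grid_search(ts, cfg)
        model = train(ts, params, cfg)
        labels = predict_map(model, stack, masks)
        pred_disturbed = labels == DISTURBED_LABEL
        negatives = masks.valid & ~truly_disturbed
        fp = int((pred_disturbed & negatives).sum())
        out[f"fpr_{name}"] = fp / negatives.sum() if negatives.sum() else 0.0
    return out
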