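"""End-to-end orchestration: segment, quantify batches, evaluate.

The segmentation chain for one image is: greyscale conversion -> multiscale
BIF labelling -> local-histogram features -> random-forest pixel labels ->
morphological cleanup -> colony metrics.  This module wires the stages
together, tracks a configuration fingerprint so a model is never applied to
features computed under different settings, and logs per-stage timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation
from .bif import compute_features
from .classifier import ColonyClassifier, FeatureConfig
from .io import CALIBRATION_PROFILES, DEFAULT_PROFILE, GrayImage, load_image
from .postprocess import (
    DEFAULT_MIN_HOLE_FILL,
    DEFAULT_MIN_OBJECT,
    ColonyLabelMap,
    ColonyMetrics,
    cleanup,
    metrics,
)

__all__ = ["PipelineConfig", "segment", "quantify_batch", "evaluate"]

logger = logging.getLogger("colonyscan")

_IMAGE_EXTS = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the segmentation chain in one serialisable place."""

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    n_trees: int = 20
    mtry: int = 5
    seed: int | None = 0
    min_object: int = DEFAULT_MIN_OBJECT
    min_hole_fill: int = DEFAULT_MIN_HOLE_FILL
    calibration_profile: str = DEFAULT_PROFILE
    calibration_um2: float | None = None

    def area_per_pixel_um2(self) -> float:
        if self.calibration_um2 is not None:
            return self.calibration_um2
        return CALIBRATION_PROFILES[self.calibration_profile]

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "feature": self.feature.fingerprint(),
                "n_trees": self.n_trees,
                "mtry": self.mtry,
                "seed": self.seed,
                "min_object": self.min_object,
                "min_hole_fill": self.min_hole_fill,
                "calibration": self.area_per_pixel_um2(),
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


def _as_gray(image, config: PipelineConfig) -> GrayImage:
    if isinstance(image, GrayImage):
        return image
    if isinstance(image, (str, os.PathLike)):
        return load_image(
            image,
            profile=config.calibration_profile,
            calibration=config.calibration_um2,
        )
    return GrayImage(np.asarray(image), config.area_per_pixel_um2())


def segment(
    image,
    model: ColonyClassifier,
    config: PipelineConfig | None = None,
) -> tuple[ColonyLabelMap, ColonyMetrics]:
    """Run the full chain on one image (path, array or :class:`GrayImage`).

    Raises
    ------
    ValueError
        If the model's feature fingerprint does not match the config.
    """
    config = config or PipelineConfig()
    if model.feature_config.fingerprint() != config.feature.fingerprint():
        raise ValueError(
            "model feature configuration does not match pipeline config"
        )
    gray = _as_gray(image, config)
    logger.debug("pipeline fingerprint %s", config.fingerprint())
    stages = {}
    t0 = time.perf_counter()
    fs = compute_features(
        gray.pixels, config.feature.scales, config.feature.epsilon,
        config.feature.window,
    )
    stages["features_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    raw = model.predict_mask(fs)
    stages["classify_s"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    clm = cleanup(
        raw,
        config.min_object,
        config.min_hole_fill,
        area_per_pixel_um2=gray.area_per_pixel_um2,
    )
    stages["cleanup_s"] = time.perf_counter() - t0
    logger.info(
        "segmented %s px image in %.2fs %s",
        gray.pixels.shape,
        sum(stages.values()),
        stages,
    )
    return clm, metrics(clm)


def _list_images(directory) -> list[Path]:
    d = Path(directory)
    if not d.is_dir():
        raise ValueError(f"not a directory: {directory}")
    files = sorted(p for p in d.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
    if not files:
        raise ValueError(f"no PNG/TIFF images found in {directory}")
    return files


def quantify_batch(
    directory,
    model: ColonyClassifier,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Segment every image in a directory; one metrics row per image.

    Columns mirror a culture-monitoring table: detected colony count, total
    and mean colony area (mm²) and confluency.
    """
    config = config or PipelineConfig()
    rows = []
    for path in _list_images(directory):
        _, m = segment(path, model, config)
        rows.append(
            {
                "image": path.name,
                "n_colonies": m.n_colonies,
                "total_area_mm2": m.total_area_mm2,
                "mean_area_mm2": m.mean_area_mm2,
                "confluency": m.confluency,
            }
        )
    return pd.DataFrame(rows)


def _read_mask(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def evaluate(pred_dir, ref_dir) -> evaluation.EvaluationReport:
    """Compare predicted to reference mask files matched by filename.

    Unmatched or shape-mismatched pairs are reported in a warning and
    skipped; the remaining pairs feed
    :func:`colonyscan.evaluation.confluency_report`.
    """
    preds = {p.name: p for p in _list_images(pred_dir)}
    refs = {p.name: p for p in _list_images(ref_dir)}
    unmatched = sorted(set(preds) ^ set(refs))
    if unmatched:
        warnings.warn(f"skipping unmatched mask files: {unmatched}")
    pairs = []
    for name in sorted(set(preds) & set(refs)):
        p, r = _read_mask(preds[name]), _read_mask(refs[name])
        if p.shape != r.shape:
            warnings.warn(
                f"skipping {name}: shape mismatch {p.shape} vs {r.shape}"
            )
            continue
        pairs.append((p, r))
    if not pairs:
        raise ValueError("no comparable mask pairs found")
    return evaluation.confluency_report(pairs)
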