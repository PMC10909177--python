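"""End-to-end dataflow: training and inference paths.

Training (corner-labelled images only): homography ground-truth sizing ->
feature extraction -> repeated k-fold evaluation -> final fit on all data.
Inference (uncalibrated images): detections -> features -> size prediction
-> optional allometric weight. Corners are never required at inference
time — that is the whole point of learning the conversion implicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import (
    SpeciesCatalog,
    TrayGeometry,
    TrayImageRecord,
    DetectionInstance,
)
from .errors import LayoutError, MissingCalibrationError
from .metrology import ground_truth_sizes
from .size_regression import (
    FeatureVector,
    RegressionReport,
    SizeRegressor,
    allometric_weight,
    extract_features,
    kfold_evaluate,
    predict_sizes,
    train_size_regressor,
)

logger = logging.getLogger("traymetry")


@dataclass(frozen=True)
class PipelineConfig:
    tray: TrayGeometry
    catalog: SpeciesCatalog
    regressor: str = "gbr"
    scheme: str = "minmax_input"
    k: int = 10
    repeats: int = 10
    seed: int = 0
    calibrated: bool = False
    iou_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7)
    allometric: Mapping[int, tuple[float, float]] | None = None


def training_table(records: Sequence[TrayImageRecord], config: PipelineConfig
                   ) -> tuple[list[FeatureVector], np.ndarray, pd.DataFrame]:
    """Stage 1+2: metric ground truth and features for every annotation."""
    features: list[FeatureVector] = []
    targets: list[float] = []
    rows = []
    for rec in records:
        try:
            sizes = ground_truth_sizes(rec, config.tray)
        except MissingCalibrationError as exc:
            raise MissingCalibrationError(
                f"stage ground_truth_sizes, image {rec.image_id}: {exc}"
            ) from exc
        for ann, gt in zip(rec.annotations, sizes):
            features.append(extract_features(
                ann, config.catalog, corners=rec.corners,
                include_corners=config.calibrated))
            targets.append(gt.length_cm)
            rows.append({
                "image_id": rec.image_id, "instance_id": ann.instance_id,
                "species_id": ann.species_id, "length_cm": gt.length_cm,
                "area_cm2": gt.rectified_area_cm2,
            })
    logger.info("training_table: %d images -> %d instances (calibrated=%s)",
                len(records), len(features), config.calibrated)
    return features, np.asarray(targets), pd.DataFrame(rows)


def run_training(records: Sequence[TrayImageRecord], config: PipelineConfig
                 ) -> tuple[SizeRegressor, RegressionReport]:
    """Full training path; returns the fitted model and its k-fold report."""
    features, targets, _ = training_table(records, config)
    report = kfold_evaluate(
        features, targets, regressor_spec=config.regressor,
        scheme=config.scheme, k=config.k, repeats=config.repeats,
        base_seed=config.seed)
    logger.info("kfold (%dx%d-fold, seed=%d): MAE %.4f cm, R2 %.4f",
                config.repeats, config.k, config.seed,
                report.mae_cm, report.r2)
    model = train_size_regressor(
        features, targets, regressor_spec=config.regressor,
        scheme=config.scheme, seed=config.seed)
    return model, report


def run_inference(model: SizeRegressor,
                  detections_by_image: Mapping[int, Sequence[DetectionInstance]],
                  config: PipelineConfig) -> pd.DataFrame:
    """Inference path: one output row per detection, nothing dropped.

    The detector output (species, box, mask confidence) is passed through
    unchanged with the predicted length appended; weight is present only
    when the allometric table covers the species.
    """
    if model.layout.include_corners:
        raise LayoutError(
            "model was trained with corner features; inference is "
            "corner-free by contract")
    rows = []
    for image_id, dets in detections_by_image.items():
        if not dets:
            continue
        feats = [extract_features(d, config.catalog) for d in dets]
        lengths = predict_sizes(model, feats)
        for det, length in zip(dets, lengths):
            weight = np.nan
            if config.allometric is not None and det.species_id in config.allometric:
                weight = allometric_weight(float(length), det.species_id,
                                           config.allometric)
            rows.append({
                "image_id": image_id,
                "species_id": det.species_id,
                "species": config.catalog.name_of(det.species_id),
                "confidence": det.confidence,
                "bbox_x": det.bbox[0], "bbox_y": det.bbox[1],
                "bbox_w": det.bbox[2], "bbox_h": det.bbox[3],
                "length_cm": float(length),
                "weight_g": weight,
            })
    n_det = sum(len(d) for d in detections_by_image.values())
    logger.info("inference: %d detections -> %d rows", n_det, len(rows))
    frame = pd.DataFrame(rows, columns=[
        "image_id", "species_id", "species", "confidence",
        "bbox_x", "bbox_y", "bbox_w", "bbox_h", "length_cm", "weight_g"])
    return frame
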