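"""Mask-level detection/classification evaluation.

Predicted instances are matched to ground truth by mask IoU (computed on
polygon geometry, resolution-independent), greedily in descending
confidence. Two matching flavours are used:

* class-aware — for AP/mAP and per-class F1 (a prediction can only claim a
  ground-truth fish of its own species);
* class-agnostic — for the confusion matrix, so a detected-but-misclassified
  fish lands in an off-diagonal cell instead of disappearing; undetected
  fish land in the right-most "Missed (FN)" column.

AP uses 101-point interpolated precision (the dominant mask-mAP
convention); mAP is the unweighted mean over classes that have at least one
ground-truth instance. All ties (confidence, IoU) break toward the lowest
index for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotations_io import DetectionInstance, FishAnnotation, Ring, SpeciesCatalog
from .errors import EmptyMaskError, UndefinedAPError, ValidationError
from .metrology import rings_to_geometry

RECALL_GRID = np.linspace(0.0, 1.0, 101)


def mask_iou(a: Sequence[Ring], b: Sequence[Ring]) -> float:
    """Intersection-over-union of two polygon masks."""
    ga = rings_to_geometry(a)
    gb = rings_to_geometry(b)
    if ga.area == 0 or gb.area == 0:
        raise EmptyMaskError("mask with zero area in IoU computation")
    inter = ga.intersection(gb).area
    union = ga.union(gb).area
    return float(inter / union) if union > 0 else 0.0


@dataclass(frozen=True)
class MatchResult:
    """One-to-one prediction/ground-truth matching at a fixed IoU threshold."""

    pairs: tuple[tuple[int, int, float], ...]  # (pred idx, gt idx, IoU)
    unmatched_gt: tuple[int, ...]
    unmatched_pred: tuple[int, ...]
    iou_threshold: float


def _iou_matrix(preds: Sequence[DetectionInstance],
                gts: Sequence[FishAnnotation]) -> np.ndarray:
    mat = np.zeros((len(preds), len(gts)))
    pred_geoms = [rings_to_geometry(p.mask) for p in preds]
    gt_geoms = [rings_to_geometry(g.mask) for g in gts]
    for i, pg in enumerate(pred_geoms):
        for j, gg in enumerate(gt_geoms):
            if pg.area == 0 or gg.area == 0:
                raise EmptyMaskError("zero-area mask during matching")
            union = pg.union(gg).area
            mat[i, j] = pg.intersection(gg).area / union if union > 0 else 0.0
    return mat


def match_instances(preds: Sequence[DetectionInstance],
                    gts: Sequence[FishAnnotation],
                    iou_threshold: float,
                    class_agnostic: bool = False) -> MatchResult:
    """Greedy one-to-one matching in descending confidence.

    Each prediction claims its highest-IoU still-unmatched ground truth with
    IoU >= threshold (same species unless ``class_agnostic``). Equal
    confidences break by prediction index, equal IoUs by ground-truth index.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValidationError(f"IoU threshold {iou_threshold} outside (0, 1)")
    iou = _iou_matrix(preds, gts)
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    gt_taken = [False] * len(gts)
    pairs = []
    matched_preds = set()
    for pi in order:
        best_j, best_iou = -1, -1.0
        for j in range(len(gts)):
            if gt_taken[j]:
                continue
            if not class_agnostic and preds[pi].species_id != gts[j].species_id:
                continue
            if iou[pi, j] >= iou_threshold and iou[pi, j] > best_iou:
                best_j, best_iou = j, iou[pi, j]
        if best_j >= 0:
            gt_taken[best_j] = True
            matched_preds.add(pi)
            pairs.append((pi, best_j, float(best_iou)))
    return MatchResult(
        pairs=tuple(pairs),
        unmatched_gt=tuple(j for j in range(len(gts)) if not gt_taken[j]),
        unmatched_pred=tuple(i for i in range(len(preds))
                             if i not in matched_preds),
        iou_threshold=iou_threshold,
    )


def _class_tp_flags(preds_by_image: Sequence[Sequence[DetectionInstance]],
                    gts_by_image: Sequence[Sequence[FishAnnotation]],
                    species_id: int, iou_threshold: float
                    ) -> tuple[list[tuple[float, bool]], int]:
    """Pooled (confidence, is_tp) flags for one class, plus its gt count."""
    flags: list[tuple[float, bool]] = []
    n_gt = 0
    for preds, gts in zip(preds_by_image, gts_by_image):
        cls_preds = [p for p in preds if p.species_id == species_id]
        cls_gts = [g for g in gts if g.species_id == species_id]
        n_gt += len(cls_gts)
        if not cls_preds:
            continue
        res = match_instances(cls_preds, cls_gts, iou_threshold) if cls_gts \
            else MatchResult((), (), tuple(range(len(cls_preds))), iou_threshold)
        matched = {pi for pi, _, _ in res.pairs}
        for i, p in enumerate(cls_preds):
            flags.append((p.confidence, i in matched))
    return flags, n_gt


def average_precision(preds_by_image: Sequence[Sequence[DetectionInstance]],
                      gts_by_image: Sequence[Sequence[FishAnnotation]],
                      species_id: int, iou_threshold: float) -> float:
    """101-point interpolated AP for one class, pooled over images."""
    flags, n_gt = _class_tp_flags(preds_by_image, gts_by_image,
                                  species_id, iou_threshold)
    if n_gt == 0:
        raise UndefinedAPError(f"no ground truth of species {species_id}")
    if not flags:
        return 0.0
    flags.sort(key=lambda t: -t[0])  # stable: confidence desc, pool order
    tp = np.cumsum([f for _, f in flags])
    fp = np.cumsum([not f for _, f in flags])
    recall = tp / n_gt
    precision = tp / (tp + fp)
    interp = np.zeros_like(RECALL_GRID)
    for i, r in enumerate(RECALL_GRID):
        mask = recall >= r - 1e-12
        interp[i] = precision[mask].max() if mask.any() else 0.0
    return float(interp.mean())


def map_curve(preds_by_image: Sequence[Sequence[DetectionInstance]],
              gts_by_image: Sequence[Sequence[FishAnnotation]],
              thresholds: Sequence[float],
              catalog: SpeciesCatalog) -> dict[float, float]:
    """mAP at each IoU threshold (mean of defined per-class APs).

    Classes with zero ground truth are skipped and recorded nowhere in the
    mean; thresholds must be strictly increasing in (0, 1).
    """
    thr = list(thresholds)
    if any(not (0 < t < 1) for t in thr) or any(
            b <= a for a, b in zip(thr, thr[1:])):
        raise ValidationError(f"thresholds must be strictly increasing in (0,1): {thr}")
    out: dict[float, float] = {}
    for t in thr:
        aps = []
        for sid, _ in catalog.entries:
            try:
                aps.append(average_precision(preds_by_image, gts_by_image, sid, t))
            except UndefinedAPError:
                continue
        out[t] = float(np.mean(aps)) if aps else float("nan")
    return out


@dataclass(frozen=True)
class ConfusionWithFN:
    """Row-normalized confusion matrix with a trailing Missed (FN) column.

    ``matrix`` holds percentages (rows sum to 100); ``counts`` the raw
    integers; ``empty_rows`` flags species with zero ground-truth instances
    (their rows are all-zero).
    """

    matrix: np.ndarray
    counts: np.ndarray
    empty_rows: tuple[int, ...]
    labels: tuple[str, ...]

    @property
    def column_labels(self) -> tuple[str, ...]:
        return self.labels + ("Missed (FN)",)


def confusion_with_fn(preds_by_image: Sequence[Sequence[DetectionInstance]],
                      gts_by_image: Sequence[Sequence[FishAnnotation]],
                      catalog: SpeciesCatalog,
                      iou_threshold: float = 0.5) -> ConfusionWithFN:
    """Per-species confusion under class-agnostic matching.

    Each ground-truth fish contributes to its row: the column of the matched
    prediction's species (diagonal = correctly classified, off-diagonal =
    detected but misclassified), or the final Missed (FN) column if no
    prediction matched it.
    """
    k = len(catalog)
    counts = np.zeros((k, k + 1), dtype=int)
    for preds, gts in zip(preds_by_image, gts_by_image):
        res = match_instances(preds, gts, iou_threshold, class_agnostic=True)
        gt_to_pred = {j: pi for pi, j, _ in res.pairs}
        for j, gt in enumerate(gts):
            if j in gt_to_pred:
                counts[gt.species_id, preds[gt_to_pred[j]].species_id] += 1
            else:
                counts[gt.species_id, k] += 1
    row_sums = counts.sum(axis=1)
    matrix = np.zeros_like(counts, dtype=float)
    nonzero = row_sums > 0
    matrix[nonzero] = 100.0 * counts[nonzero] / row_sums[nonzero, None]
    return ConfusionWithFN(
        matrix=matrix, counts=counts,
        empty_rows=tuple(int(i) for i in np.flatnonzero(~nonzero)),
        labels=catalog.names,
    )


def per_class_f1(preds_by_image: Sequence[Sequence[DetectionInstance]],
                 gts_by_image: Sequence[Sequence[FishAnnotation]],
                 catalog: SpeciesCatalog,
                 iou_threshold: float = 0.5) -> dict[int, float]:
    """F1 per species from pooled TP/FP/FN under class-aware matching."""
    tp = np.zeros(len(catalog), int)
    fp = np.zeros(len(catalog), int)
    fn = np.zeros(len(catalog), int)
    for preds, gts in zip(preds_by_image, gts_by_image):
        res = match_instances(preds, gts, iou_threshold, class_agnostic=False)
        for pi, j, _ in res.pairs:
            tp[preds[pi].species_id] += 1
        for pi in res.unmatched_pred:
            fp[preds[pi].species_id] += 1
        for j in res.unmatched_gt:
            fn[gts[j].species_id] += 1
    out: dict[int, float] = {}
    for sid, _ in catalog.entries:
        denom = 2 * tp[sid] + fp[sid] + fn[sid]
        out[sid] = float(2 * tp[sid] / denom) if denom > 0 else 0.0
    return out
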