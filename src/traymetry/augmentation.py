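"""Annotation-level augmentation and species-balancing plans.

Augmentation ops are rigid motions — a rotation about the image centre
followed by a translation — applied to masks, polylines, corners and boxes
(boxes are recomputed as the hull of the transformed mask). Instances whose
remaining in-canvas mask area falls below a visibility fraction of the
original area are dropped; pixels are never touched (the tray datasets this
emulates are augmented at the annotation level, with image rendering left to
the training toolchain).

Because several species share a tray, per-species counts cannot be balanced
exactly by whole-image augmentation. The planner replaces the manual
balancing of the original datasets with an explicit greedy objective: repeat
the image whose duplication most reduces the max/min species-count ratio,
until the target ratio or the op budget is reached. Rotation angles cycle
round-robin through the configured set (default 15°, 45°, 90° and the other
multiples, matching common tray-augmentation practice) and translation
magnitudes are drawn 5–50 px from a seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely

from .annotations_io import (
    FishAnnotation,
    SpeciesCatalog,
    TrayImageRecord,
    canonicalize_corners,
)
from .errors import InvalidOpError, ValidationError
from .metrology import rings_to_geometry


@dataclass(frozen=True)
class OpCatalog:
    """Configured augmentation ranges."""

    rotations_deg: tuple[float, ...] = (0.0, 15.0, 45.0, 90.0, 135.0,
                                        180.0, 225.0, 270.0, 315.0)
    translation_min_px: float = 5.0
    translation_max_px: float = 50.0


@dataclass(frozen=True)
class AugmentationOp:
    """One rigid op: rotate about image centre, then translate."""

    rotation_deg: float
    translation: tuple[float, float]

    def inverse(self) -> "AugmentationOp":
        """Undo in reverse order: -translation first, then -rotation.

        Because both are expressed in one op (rotation then translation),
        the inverse is rotation -r with translation -R(-r) t.
        """
        r = math.radians(-self.rotation_deg)
        dx, dy = self.translation
        c, s = math.cos(r), math.sin(r)
        return AugmentationOp(
            rotation_deg=-self.rotation_deg,
            translation=(-(c * dx - s * dy), -(s * dx + c * dy)),
        )


def validate_op(op: AugmentationOp, catalog: OpCatalog) -> None:
    rot = op.rotation_deg % 360.0
    allowed = {r % 360.0 for r in catalog.rotations_deg}
    if not any(math.isclose(rot, a, abs_tol=1e-9) for a in allowed):
        raise InvalidOpError(
            f"rotation {op.rotation_deg} not in configured set {sorted(allowed)}")
    mag = math.hypot(*op.translation)
    if mag > catalog.translation_max_px + 1e-9:
        raise InvalidOpError(
            f"translation magnitude {mag:.1f} exceeds {catalog.translation_max_px}")
    if mag > 1e-9 and mag < catalog.translation_min_px - 1e-9:
        raise InvalidOpError(
            f"translation magnitude {mag:.1f} below {catalog.translation_min_px}")


def _transform(points: np.ndarray, op: AugmentationOp,
               centre: tuple[float, float]) -> np.ndarray:
    r = math.radians(op.rotation_deg)
    c, s = math.cos(r), math.sin(r)
    rot = np.array([[c, -s], [s, c]])
    shifted = np.asarray(points, float) - centre
    return shifted @ rot.T + centre + np.asarray(op.translation)


def apply_op(record: TrayImageRecord, op: AugmentationOp,
             catalog: OpCatalog | None = None,
             visibility_fraction: float = 0.5) -> TrayImageRecord:
    """Apply one op to every geometry of a record.

    Instances whose in-canvas mask area drops below
    ``visibility_fraction`` x original area are removed. When an
    :class:`OpCatalog` is supplied the op is validated against its ranges
    first; without one any rigid motion is applied.
    """
    if catalog is not None:
        validate_op(op, catalog)
    centre = (record.width / 2.0, record.height / 2.0)
    canvas = shapely.box(0, 0, record.width, record.height)

    corners = record.corners
    if corners is not None:
        corners = canonicalize_corners(_transform(corners.as_array(), op, centre))

    kept: list[FishAnnotation] = []
    for ann in record.annotations:
        new_rings = tuple(
            tuple(map(tuple, _transform(np.asarray(ring), op, centre)))
            for ring in ann.mask
        )
        orig_area = rings_to_geometry(ann.mask).area
        visible = rings_to_geometry(new_rings).intersection(canvas).area
        if orig_area <= 0 or visible / orig_area < visibility_fraction:
            continue
        allv = np.vstack([np.asarray(r) for r in new_rings])
        x0, y0 = allv.min(axis=0)
        x1, y1 = allv.max(axis=0)
        poly = ann.size_polyline
        if poly is not None:
            poly = tuple(map(tuple, _transform(np.asarray(poly), op, centre)))
        kept.append(FishAnnotation(
            instance_id=ann.instance_id,
            species_id=ann.species_id,
            mask=new_rings,
            bbox=(float(x0), float(y0), float(x1 - x0), float(y1 - y0)),
            size_polyline=poly,
        ))
    return TrayImageRecord(
        image_id=record.image_id, width=record.width, height=record.height,
        corners=corners, annotations=tuple(kept),
    )


def species_counts(records: Sequence[TrayImageRecord],
                   catalog: SpeciesCatalog) -> np.ndarray:
    """Exact per-species instance counts, in catalog order."""
    counts = np.zeros(len(catalog), dtype=int)
    for rec in records:
        for ann in rec.annotations:
            counts[ann.species_id] += 1
    return counts


def balance_ratio(counts: np.ndarray) -> float:
    """max/min over species with at least one instance; inf if none."""
    pos = counts[counts > 0]
    if pos.size == 0:
        return float("inf")
    return float(pos.max() / pos.min())


@dataclass(frozen=True)
class AugmentationPlan:
    """Greedy balancing plan: ops per image + exact count bookkeeping."""

    ops_by_image: tuple[tuple[AugmentationOp, ...], ...]
    base_counts: np.ndarray
    achieved_counts: np.ndarray
    achieved_ratio: float
    warnings: tuple[str, ...] = ()

    @property
    def total_ops(self) -> int:
        return sum(len(ops) for ops in self.ops_by_image)


def _draw_op(op_catalog: OpCatalog, image_index: int, k: int,
             seed: int) -> AugmentationOp:
    """Deterministic op for the k-th augmentation of one image."""
    rotations = [r for r in op_catalog.rotations_deg if r % 360.0 != 0.0] \
        or list(op_catalog.rotations_deg)
    rot = rotations[k % len(rotations)]
    rng = np.random.default_rng([seed, image_index, k])
    mag = rng.uniform(op_catalog.translation_min_px, op_catalog.translation_max_px)
    ang = rng.uniform(0.0, 2.0 * math.pi)
    return AugmentationOp(rotation_deg=rot,
                          translation=(mag * math.cos(ang), mag * math.sin(ang)))


def plan_balanced_augmentation(records: Sequence[TrayImageRecord],
                               op_catalog: OpCatalog = OpCatalog(),
                               target_ratio: float = 2.0,
                               max_ops_per_image: int = 40,
                               max_total_ops: int = 1000,
                               seed: int = 0,
                               catalog: SpeciesCatalog | None = None,
                               visibility_fraction: float = 0.5
                               ) -> AugmentationPlan:
    """Greedy species-balancing plan.

    While the max/min count ratio exceeds ``target_ratio`` and budget
    remains, augment the image whose added (surviving) instances most
    reduce the ratio; ties break toward the lowest image index. The greedy
    step is simulated with :func:`apply_op`, so clipped-away instances are
    never counted — replaying the plan reproduces the claimed counts
    exactly. The achieved ratio never exceeds the initial ratio.
    """
    if catalog is None:
        max_sid = max((a.species_id for r in records for a in r.annotations),
                      default=-1)
        catalog = SpeciesCatalog.from_names(
            [f"species_{i}" for i in range(max_sid + 1)])
    base = species_counts(records, catalog)
    if base.sum() == 0:
        raise ValidationError("cannot balance a dataset with zero instances")
    warnings = tuple(
        f"species {catalog.name_of(int(i))} present in zero images: unbalanceable"
        for i in np.flatnonzero(base == 0)
    )

    counts = base.copy()
    ops: list[list[AugmentationOp]] = [[] for _ in records]
    while balance_ratio(counts) > target_ratio and sum(map(len, ops)) < max_total_ops:
        # key: smallest new ratio; ties prefer the candidate that raises the
        # scarcest counts (lexicographically largest sorted count vector) so
        # the loop keeps making progress when the min spans several species;
        # remaining ties go to the lowest image index
        best = None  # (key, image index, op, contribution)
        current = balance_ratio(counts)
        for i, rec in enumerate(records):
            if len(ops[i]) >= max_ops_per_image or not rec.annotations:
                continue
            op = _draw_op(op_catalog, i, len(ops[i]), seed)
            contrib = species_counts(
                [apply_op(rec, op, visibility_fraction=visibility_fraction)],
                catalog)
            new_counts = counts + contrib
            ratio = balance_ratio(new_counts)
            if ratio > current + 1e-12:
                continue  # a step may never worsen the balance
            key = (ratio, tuple(-c for c in sorted(new_counts)), i)
            if best is None or key < best[0]:
                best = (key, i, op, contrib)
        if best is None:
            break  # every available step would worsen the ratio
        _, i, op, contrib = best
        ops[i].append(op)
        counts = counts + contrib

    return AugmentationPlan(
        ops_by_image=tuple(tuple(o) for o in ops),
        base_counts=base,
        achieved_counts=counts,
        achieved_ratio=balance_ratio(counts),
        warnings=warnings,
    )


def replay_plan(records: Sequence[TrayImageRecord], plan: AugmentationPlan,
                visibility_fraction: float = 0.5) -> list[TrayImageRecord]:
    """Materialize a plan: augmented records (originals not included)."""
    out: list[TrayImageRecord] = []
    next_id = max((r.image_id for r in records), default=-1) + 1
    for rec, rec_ops in zip(records, plan.ops_by_image):
        for op in rec_ops:
            aug = apply_op(rec, op, visibility_fraction=visibility_fraction)
            out.append(TrayImageRecord(
                image_id=next_id, width=aug.width, height=aug.height,
                corners=aug.corners, annotations=aug.annotations,
            ))
            next_id += 1
    return out


def plan_to_jsonable(plan: AugmentationPlan) -> dict:
    return {
        "ops_by_image": [
            [{"rotation_deg": op.rotation_deg, "translation": list(op.translation)}
             for op in ops]
            for ops in plan.ops_by_image
        ],
        "base_counts": plan.base_counts.tolist(),
        "achieved_counts": plan.achieved_counts.tolist(),
        "achieved_ratio": plan.achieved_ratio,
        "warnings": list(plan.warnings),
    }
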