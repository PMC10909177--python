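"""COCO-dialect annotation I/O and the shared domain types.

The on-disk format is standard MS-COCO instance JSON with two extension keys
that plain COCO readers ignore:

* per-annotation ``"size_polyline"``: flat ``[x1, y1, x2, y2, ...]`` pixel
  vertex list tracing the fish from the mouth to the base of the tail;
* per-image ``"tray_corners"``: four ``[x, y]`` pixel points marking the
  rectangle spanned by the start of the tray handles.

Coordinates follow COCO practice: origin at the top-left pixel corner, x
rightward, y downward, continuous (sub-pixel positions are allowed). Boxes
are ``(x_min, y_min, width, height)``. Masks are stored as COCO polygon
lists; RLE segmentations (uncompressed counts lists or compressed LEB128
strings) are accepted on read and converted to polygons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DegenerateQuadError,
    ParseError,
    ValidationError,
)

Point = tuple[float, float]
Ring = tuple[Point, ...]

#: absolute tolerance (px) for "bbox encloses mask" and collinearity tests
GEOM_TOL = 1e-6


# ---------------------------------------------------------------------------
# small geometry helpers shared by the domain types
# ---------------------------------------------------------------------------

def _as_points(seq: Iterable[Sequence[float]]) -> tuple[Point, ...]:
    return tuple((float(p[0]), float(p[1])) for p in seq)


def _flat_to_points(flat: Sequence[float]) -> tuple[Point, ...]:
    if len(flat) % 2 != 0:
        raise ValidationError(f"odd-length coordinate list ({len(flat)})")
    return tuple(
        (float(flat[i]), float(flat[i + 1])) for i in range(0, len(flat), 2)
    )


def _points_to_flat(points: Sequence[Point]) -> list[float]:
    out: list[float] = []
    for x, y in points:
        out.extend((float(x), float(y)))
    return out


def _triangle_area2(a: Point, b: Point, c: Point) -> float:
    """Twice the signed triangle area (positive = clockwise on screen)."""
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def _ring_is_simple(ring: Ring) -> bool:
    """Non-self-intersection test for one polygon ring (shapely validity)."""
    import shapely

    if len(ring) < 3:
        return False
    poly = shapely.Polygon(ring)
    return bool(poly.is_valid and poly.area > 0)


def shoelace_area(ring: Sequence[Point]) -> float:
    """Unsigned shoelace area of a single ring."""
    arr = np.asarray(ring, dtype=float)
    x, y = arr[:, 0], arr[:, 1]
    return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesCatalog:
    """Ordered species registry; order fixes the one-hot column order."""

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.entries]
        names = [name for _, name in self.entries]
        if ids != list(range(len(ids))):
            raise ValidationError(
                f"species ids must be contiguous from 0, got {ids}"
            )
        if len(set(names)) != len(names):
            raise ValidationError("species names must be unique")

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "SpeciesCatalog":
        return cls(tuple((i, str(n)) for i, n in enumerate(names)))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.entries)

    def name_of(self, species_id: int) -> str:
        return self.entries[species_id][1]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, species_id: object) -> bool:
        return isinstance(species_id, (int, np.integer)) and 0 <= int(species_id) < len(self)


@dataclass(frozen=True)
class TrayGeometry:
    """Real-world tray rectangle in centimetres; width >= height."""

    width_cm: float
    height_cm: float

    def __post_init__(self) -> None:
        w, h = float(self.width_cm), float(self.height_cm)
        if not (w > 0 and h > 0):
            raise ValidationError("tray dimensions must be strictly positive")
        if h > w:  # canonicalize so width is the long side
            w, h = h, w
        object.__setattr__(self, "width_cm", w)
        object.__setattr__(self, "height_cm", h)

    @property
    def corners_cm(self) -> tuple[Point, Point, Point, Point]:
        """TL, TR, BR, BL of the metric tray plane."""
        w, h = self.width_cm, self.height_cm
        return ((0.0, 0.0), (w, 0.0), (w, h), (0.0, h))


@dataclass(frozen=True)
class CornerQuad:
    """Tray-handle rectangle as seen in the image: TL, TR, BR, BL order."""

    points: tuple[Point, Point, Point, Point]

    def __post_init__(self) -> None:
        pts = _as_points(self.points)
        if len(pts) != 4:
            raise DegenerateQuadError(f"need 4 corner points, got {len(pts)}")
        object.__setattr__(self, "points", pts)
        _check_quad(pts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


def _check_quad(pts: Sequence[Point]) -> None:
    if len({p for p in pts}) != 4:
        raise DegenerateQuadError("corner points must be distinct")
    # no three collinear
    from itertools import combinations

    for a, b, c in combinations(pts, 3):
        if abs(_triangle_area2(a, b, c)) <= GEOM_TOL:
            raise DegenerateQuadError(
                f"collinear corner triple {a}, {b}, {c}"
            )
    # convex in the given cyclic order
    signs = []
    for i in range(4):
        a, b, c = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
        signs.append(math.copysign(1.0, _triangle_area2(a, b, c)))
    if len(set(signs)) != 1:
        raise DegenerateQuadError("corner quad is not convex in this order")


def canonicalize_corners(points: Iterable[Sequence[float]]) -> CornerQuad:
    """Order four corner points canonically (TL, TR, BR, BL).

    Points are sorted by angle about their centroid and the cycle is rotated
    so it starts at the point with lexicographically smallest (y, x) — the
    visual top-left. The result is permutation-invariant and idempotent.
    """
    pts = _as_points(points)
    if len(pts) != 4:
        raise DegenerateQuadError(f"need 4 corner points, got {len(pts)}")
    if len(set(pts)) != 4:
        raise DegenerateQuadError("corner points must be distinct")
    cx = sum(p[0] for p in pts) / 4.0
    cy = sum(p[1] for p in pts) / 4.0
    ordered = sorted(pts, key=lambda p: math.atan2(p[1] - cy, p[0] - cx))
    start = min(range(4), key=lambda i: (ordered[i][1], ordered[i][0]))
    ordered = ordered[start:] + ordered[:start]
    return CornerQuad(tuple(ordered))  # type: ignore[arg-type]


def _check_bbox_encloses(bbox: tuple[float, float, float, float],
                         rings: Sequence[Ring], what: str) -> None:
    x, y, w, h = bbox
    if not (w > 0 and h > 0):
        raise ValidationError(f"{what}: bbox width/height must be positive")
    for ring in rings:
        for px, py in ring:
            if not (x - GEOM_TOL <= px <= x + w + GEOM_TOL
                    and y - GEOM_TOL <= py <= y + h + GEOM_TOL):
                raise ValidationError(
                    f"{what}: bbox {bbox} does not enclose mask vertex "
                    f"({px}, {py})"
                )


@dataclass(frozen=True)
class FishAnnotation:
    """One ground-truth fish: mask, box, species and size polyline (pixels)."""

    instance_id: int
    species_id: int
    mask: tuple[Ring, ...]
    bbox: tuple[float, float, float, float]
    size_polyline: tuple[Point, ...] | None = None

    def __post_init__(self) -> None:
        mask = tuple(_as_points(ring) for ring in self.mask)
        if not mask:
            raise ValidationError("annotation must have at least one mask ring")
        for ring in mask:
            if len(ring) < 3:
                raise ValidationError("mask ring needs >= 3 vertices")
            if not _ring_is_simple(ring):
                raise ValidationError(
                    f"self-intersecting mask ring for instance {self.instance_id}"
                )
        bbox = tuple(float(v) for v in self.bbox)
        _check_bbox_encloses(bbox, mask, f"instance {self.instance_id}")  # type: ignore[arg-type]
        poly = self.size_polyline
        if poly is not None:
            poly = _as_points(poly)
            if len(poly) < 2:
                raise ValidationError("size polyline needs >= 2 vertices")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "bbox", bbox)
        object.__setattr__(self, "size_polyline", poly)


@dataclass(frozen=True)
class DetectionInstance:
    """One predicted fish (the network output side of the pipeline)."""

    species_id: int
    mask: tuple[Ring, ...]
    bbox: tuple[float, float, float, float]
    confidence: float

    def __post_init__(self) -> None:
        mask = tuple(_as_points(ring) for ring in self.mask)
        bbox = tuple(float(v) for v in self.bbox)
        _check_bbox_encloses(bbox, mask, "detection")  # type: ignore[arg-type]
        conf = float(self.confidence)
        if not (0.0 <= conf <= 1.0):
            raise ValidationError(f"confidence {conf} outside [0, 1]")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "bbox", bbox)
        object.__setattr__(self, "confidence", conf)


@dataclass(frozen=True)
class TrayImageRecord:
    """One tray image: pixel size, optional corner quad, fish annotations."""

    image_id: int
    width: int
    height: int
    corners: CornerQuad | None
    annotations: tuple[FishAnnotation, ...]

    def __post_init__(self) -> None:
        anns = tuple(self.annotations)
        ids = [a.instance_id for a in anns]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"duplicate instance ids in image {self.image_id}: {ids}"
            )
        object.__setattr__(self, "annotations", anns)


# ---------------------------------------------------------------------------
# RLE support (accepted on read, converted to polygons)
# ---------------------------------------------------------------------------

def _rle_decode_counts(counts: Sequence[int], h: int, w: int) -> np.ndarray:
    grid = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for run in counts:
        grid[pos:pos + run] = val
        pos += run
        val = not val
    # COCO RLE is column-major
    return grid.reshape((w, h)).T


def _rle_decompress(s: str) -> list[int]:
    """Decode COCO's LEB128-style compressed RLE counts string."""
    counts: list[int] = []
    i = 0
    while i < len(s):
        x = 0
        k = 0
        more = True
        while more:
            c = ord(s[i]) - 48
            x |= (c & 0x1F) << (5 * k)
            more = bool(c & 0x20)
            i += 1
            k += 1
        if x & (1 << (5 * k - 1)):
            x -= 1 << (5 * k)
        if len(counts) > 2:
            x += counts[-2]
        counts.append(x)
    return counts


def _rle_to_rings(seg: Mapping, h: int, w: int) -> tuple[Ring, ...]:
    from skimage import measure

    counts = seg["counts"]
    if isinstance(counts, str):
        counts = _rle_decompress(counts)
    grid = _rle_decode_counts(list(counts), h, w)
    padded = np.pad(grid.astype(float), 1)
    rings = []
    for contour in measure.find_contours(padded, 0.5):
        # (row, col) -> (x, y), undo padding
        ring = [(float(c - 1), float(r - 1)) for r, c in contour]
        if len(ring) >= 3:
            rings.append(tuple(ring[:-1]))  # drop closing duplicate
    if not rings:
        raise ValidationError("RLE mask decoded to an empty polygon set")
    return tuple(rings)


# ---------------------------------------------------------------------------
# dataset read / write
# ---------------------------------------------------------------------------

def _segmentation_to_rings(seg, img_h: int, img_w: int) -> tuple[Ring, ...]:
    if isinstance(seg, Mapping):  # RLE
        return _rle_to_rings(seg, img_h, img_w)
    return tuple(_flat_to_points(ring) for ring in seg)


def read_dataset(path: str | Path, catalog: SpeciesCatalog) -> list[TrayImageRecord]:
    """Read a COCO-dialect annotation file into tray records.

    Records preserve file order. Missing ``tray_corners`` / ``size_polyline``
    keys yield absent fields. Annotations referencing a species id outside
    the catalog raise a :class:`ValidationError` listing the offenders.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"{path}: malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc

    bad = sorted({
        ann["category_id"] for ann in data.get("annotations", [])
        if ann["category_id"] not in catalog
    })
    if bad:
        raise ValidationError(f"unknown species ids in {path}: {bad}")

    by_image: dict[int, list[dict]] = {}
    for ann in data.get("annotations", []):
        by_image.setdefault(ann["image_id"], []).append(ann)

    records: list[TrayImageRecord] = []
    for img in data.get("images", []):
        w, h = int(img["width"]), int(img["height"])
        corners = None
        if img.get("tray_corners") is not None:
            corners = canonicalize_corners(img["tray_corners"])
        anns = []
        for ann in by_image.get(img["id"], []):
            poly = ann.get("size_polyline")
            anns.append(FishAnnotation(
                instance_id=int(ann.get("instance_id", ann["id"])),
                species_id=int(ann["category_id"]),
                mask=_segmentation_to_rings(ann["segmentation"], h, w),
                bbox=tuple(float(v) for v in ann["bbox"]),  # type: ignore[arg-type]
                size_polyline=_flat_to_points(poly) if poly is not None else None,
            ))
        records.append(TrayImageRecord(
            image_id=int(img["id"]), width=w, height=h,
            corners=corners, annotations=tuple(anns),
        ))
    return records


def write_dataset(records: Sequence[TrayImageRecord], catalog: SpeciesCatalog,
                  path: str | Path) -> None:
    """Write records as COCO-dialect JSON (plain-COCO readable)."""
    images = []
    annotations = []
    next_ann_id = 1
    for rec in records:
        img_entry: dict = {
            "id": rec.image_id,
            "width": rec.width,
            "height": rec.height,
            "file_name": f"tray_{rec.image_id:06d}.png",
        }
        if rec.corners is not None:
            img_entry["tray_corners"] = [list(p) for p in rec.corners.points]
        images.append(img_entry)
        for ann in rec.annotations:
            entry: dict = {
                "id": next_ann_id,
                "instance_id": ann.instance_id,
                "image_id": rec.image_id,
                "category_id": ann.species_id,
                "segmentation": [_points_to_flat(ring) for ring in ann.mask],
                "bbox": list(ann.bbox),
                "area": sum(shoelace_area(ring) for ring in ann.mask),
                "iscrowd": 0,
            }
            if ann.size_polyline is not None:
                entry["size_polyline"] = _points_to_flat(ann.size_polyline)
            annotations.append(entry)
            next_ann_id += 1
    payload = {
        "info": {"description": "traymetry COCO-dialect annotations"},
        "licenses": [],
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": sid, "name": name, "supercategory": "fish"}
            for sid, name in catalog.entries
        ],
    }
    Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# detections files (same dialect + per-annotation "score")
# ---------------------------------------------------------------------------

def write_detections(detections: Mapping[int, Sequence[DetectionInstance]],
                     image_sizes: Mapping[int, tuple[int, int]],
                     catalog: SpeciesCatalog, path: str | Path) -> None:
    """Write predicted instances in the COCO dialect with a "score" key."""
    images = [
        {"id": iid, "width": wh[0], "height": wh[1],
         "file_name": f"tray_{iid:06d}.png"}
        for iid, wh in image_sizes.items()
    ]
    annotations = []
    next_id = 1
    for iid, dets in detections.items():
        for det in dets:
            annotations.append({
                "id": next_id,
                "image_id": iid,
                "category_id": det.species_id,
                "segmentation": [_points_to_flat(r) for r in det.mask],
                "bbox": list(det.bbox),
                "score": det.confidence,
                "iscrowd": 0,
            })
            next_id += 1
    payload = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": sid, "name": name, "supercategory": "fish"}
            for sid, name in catalog.entries
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_detections(path: str | Path,
                    catalog: SpeciesCatalog) -> dict[int, list[DetectionInstance]]:
    """Read a detections file; returns image_id -> predicted instances."""
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"{path}: malformed JSON at byte offset {exc.pos}: {exc.msg}"
        ) from exc
    sizes = {int(i["id"]): (int(i["height"]), int(i["width"]))
             for i in data.get("images", [])}
    out: dict[int, list[DetectionInstance]] = {int(i["id"]): []
                                               for i in data.get("images", [])}
    for ann in data.get("annotations", []):
        if ann["category_id"] not in catalog:
            raise ValidationError(
                f"unknown species id {ann['category_id']} in {path}")
        iid = int(ann["image_id"])
        h, w = sizes.get(iid, (0, 0))
        out.setdefault(iid, []).append(DetectionInstance(
            species_id=int(ann["category_id"]),
            mask=_segmentation_to_rings(ann["segmentation"], h, w),
            bbox=tuple(float(v) for v in ann["bbox"]),  # type: ignore[arg-type]
            confidence=float(ann.get("score", 1.0)),
        ))
    return out


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

#: explicitly arbitrary default tray size — real tray dimensions belong in config
DEFAULT_TRAY = TrayGeometry(60.0, 40.0)


def load_config(path: str | Path) -> dict:
    """Load a YAML config; returns a plain dict (see README for keys)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def tray_from_config(cfg: Mapping) -> TrayGeometry:
    tray = cfg.get("tray", {})
    return TrayGeometry(
        float(tray.get("width_cm", DEFAULT_TRAY.width_cm)),
        float(tray.get("height_cm", DEFAULT_TRAY.height_cm)),
    )


def catalog_from_config(cfg: Mapping, base_dir: str | Path = ".") -> SpeciesCatalog:
    species = cfg.get("species")
    if isinstance(species, (list, tuple)):
        return SpeciesCatalog.from_names(list(species))
    if isinstance(species, str):
        names = [ln.strip() for ln in Path(base_dir, species).read_text().splitlines()
                 if ln.strip()]
        return SpeciesCatalog.from_names(names)
    from .synthetic_scenes import DEFAULT_SPECIES_NAMES

    return SpeciesCatalog.from_names(DEFAULT_SPECIES_NAMES)
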