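"""Plane-to-plane metrology: homography estimation and metric rectification.

The tray-handle rectangle has known real-world dimensions, so the four
labelled corner points determine the projective map from image pixels to the
tray's metric plane (in cm) exactly. Lengths of size polylines, mask areas
and boxes are then measured in that plane; the resulting sizes are the
ground truth the size regressor is trained against.

The homography is estimated by the normalized direct linear transform:
both point sets are translated to their centroid and isotropically scaled to
RMS distance sqrt(2) before the 8x9 DLT system is solved by SVD. Four
correspondences make the solve exact (8 DOF), but the normalization keeps the
system well-conditioned for near-degenerate, human-clicked quads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely

from .annotations_io import (
    CornerQuad,
    FishAnnotation,
    Point,
    Ring,
    TrayGeometry,
    TrayImageRecord,
)
from .errors import (
    DegenerateQuadError,
    HorizonPointError,
    InvalidPolylineError,
    MissingCalibrationError,
)

#: max allowed corner-mapping residual, in cm
CORNER_RESIDUAL_TOL = 1e-6
#: DLT condition estimate above this attaches an ill-conditioned warning
CONDITION_WARN = 1e8
#: homogeneous w below this is treated as a horizon point
W_TOL = 1e-12


@dataclass(frozen=True, eq=False)
class Homography:
    """3x3 projective map from image pixels to tray-plane centimetres."""

    matrix: np.ndarray
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {m.shape}")
        if abs(np.linalg.det(m)) <= 1e-12:
            raise DegenerateQuadError("homography matrix is singular")
        if abs(m[2, 2]) > W_TOL:
            m = m / m[2, 2]
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))


def _normalizer(pts: np.ndarray) -> np.ndarray:
    """Hartley conditioning transform: centroid to origin, RMS radius sqrt(2)."""
    centroid = pts.mean(axis=0)
    rms = np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean())
    s = np.sqrt(2.0) / rms if rms > 0 else 1.0
    return np.array([
        [s, 0.0, -s * centroid[0]],
        [0.0, s, -s * centroid[1]],
        [0.0, 0.0, 1.0],
    ])


def estimate_homography(corners: CornerQuad, tray: TrayGeometry) -> Homography:
    """Exact 4-point homography: corner quad (px) -> tray rectangle (cm).

    Corner mapping is TL->(0,0), TR->(width,0), BR->(width,height),
    BL->(0,height). Because canonical corner order is purely visual (the
    cycle starts at the image top-left), it can start on either tray side;
    the cyclic correspondence is therefore disambiguated by pairing the
    longer pair of observed opposite edges with the tray's long side
    (``width_cm``). The residual 180-degree ambiguity is an isometry of the
    tray plane and cannot affect any length or area. Raises
    :class:`DegenerateQuadError` if the solve fails; a condition estimate
    above ``CONDITION_WARN`` attaches a warning string to the result
    instead of failing (human corner clicks are approximate).
    """
    src = corners.as_array()
    # pair long-with-long: edges (0-1, 2-3) vs (1-2, 3-0)
    e_even = np.linalg.norm(src[0] - src[1]) + np.linalg.norm(src[2] - src[3])
    e_odd = np.linalg.norm(src[1] - src[2]) + np.linalg.norm(src[3] - src[0])
    if e_odd > e_even:
        src = np.roll(src, -1, axis=0)
    dst = np.asarray(tray.corners_cm, dtype=float)

    t_src = _normalizer(src)
    t_dst = _normalizer(dst)
    src_n = (t_src @ np.column_stack([src, np.ones(4)]).T).T[:, :2]
    dst_n = (t_dst @ np.column_stack([dst, np.ones(4)]).T).T[:, :2]

    rows = []
    for (x, y), (u, v) in zip(src_n, dst_n):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    a = np.asarray(rows)
    _, s, vt = np.linalg.svd(a)
    h_n = vt[-1].reshape(3, 3)
    # exact solve leaves one ~zero singular value; condition uses the rest
    cond = s[0] / s[-2] if s[-2] > 0 else np.inf

    h = np.linalg.inv(t_dst) @ h_n @ t_src
    warnings: tuple[str, ...] = ()
    if cond > CONDITION_WARN:
        warnings = (f"ill-conditioned corner configuration (cond~{cond:.2e})",)
    try:
        result = Homography(h, warnings=warnings)
    except DegenerateQuadError as exc:
        raise DegenerateQuadError(
            f"degenerate corner configuration: {exc}") from exc

    residual = np.abs(map_points(result, src) - dst).max()
    if residual >= CORNER_RESIDUAL_TOL:
        raise DegenerateQuadError(
            f"corner residual {residual:.3e} cm exceeds {CORNER_RESIDUAL_TOL}"
        )
    return result


def map_points(h: Homography, points: Sequence[Point] | np.ndarray) -> np.ndarray:
    """Apply the projective map with perspective division; (N, 2) cm output."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hom = np.column_stack([pts, np.ones(len(pts))]) @ h.matrix.T
    w = hom[:, 2]
    bad = np.abs(w) <= W_TOL
    if bad.any():
        idx = int(np.argmax(bad))
        raise HorizonPointError(
            f"point {tuple(pts[idx])} maps to the horizon (w={w[idx]:.3e})"
        )
    return hom[:, :2] / w[:, None]


def polyline_length_cm(h: Homography, polyline: Sequence[Point]) -> float:
    """Arc length of the mapped polyline: sum of mapped segment lengths."""
    if polyline is None or len(polyline) < 2:
        raise InvalidPolylineError(
            f"polyline needs >= 2 vertices, got "
            f"{0 if polyline is None else len(polyline)}"
        )
    mapped = map_points(h, polyline)
    return float(np.linalg.norm(np.diff(mapped, axis=0), axis=1).sum())


def rings_to_geometry(rings: Sequence[Ring]) -> shapely.Geometry:
    """Build a shapely polygon from COCO-style rings, nesting holes.

    Rings are sorted by descending area; a ring covered by an already-placed
    shell becomes a hole of it, all others are shells.
    """
    polys = [shapely.Polygon(r) for r in rings]
    polys = [p if p.is_valid else p.buffer(0) for p in polys]
    order = sorted(range(len(polys)), key=lambda i: -polys[i].area)
    shells: list[int] = []
    holes: dict[int, list[int]] = {}
    for i in order:
        parent = next((s for s in shells if polys[s].contains(polys[i])), None)
        if parent is None:
            shells.append(i)
            holes[i] = []
        else:
            holes[parent].append(i)
    parts = []
    for s in shells:
        geom = polys[s]
        for hidx in holes[s]:
            geom = geom.difference(polys[hidx])
        parts.append(geom)
    return shapely.union_all(parts)


def polygon_area(rings: Sequence[Ring]) -> float:
    """Area of a multi-ring polygon, holes subtracted (shoelace per ring)."""
    return float(rings_to_geometry(rings).area)


@dataclass(frozen=True)
class GroundTruthSize:
    """Metric ground truth for one fish: length, area and box in cm."""

    instance_id: int
    length_cm: float
    rectified_area_cm2: float
    rectified_bbox: tuple[float, float, float, float]


def rectify_annotation(h: Homography, ann: FishAnnotation) -> GroundTruthSize:
    """Rectify one annotation into centimetres.

    Length is the full arc length of the mapped size polyline (bent fish are
    traced, not chorded). Area is the shoelace area of the mapped mask
    vertices — segments between mapped vertices are treated as straight,
    which is exact only in the limit of dense vertices (validated against a
    rasterization oracle in the test-suite). The box is the axis-aligned
    hull of the mapped mask.
    """
    length = polyline_length_cm(h, ann.size_polyline)
    mapped_rings = tuple(
        tuple(map(tuple, map_points(h, ring))) for ring in ann.mask
    )
    area = polygon_area(mapped_rings)  # type: ignore[arg-type]
    allv = np.vstack([np.asarray(r) for r in mapped_rings])
    x0, y0 = allv.min(axis=0)
    x1, y1 = allv.max(axis=0)
    return GroundTruthSize(
        instance_id=ann.instance_id,
        length_cm=length,
        rectified_area_cm2=area,
        rectified_bbox=(float(x0), float(y0), float(x1 - x0), float(y1 - y0)),
    )


def ground_truth_sizes(record: TrayImageRecord,
                       tray: TrayGeometry) -> list[GroundTruthSize]:
    """Metric sizes for every annotation of a corner-labelled record."""
    if record.corners is None:
        raise MissingCalibrationError(
            f"image {record.image_id} has no tray corners"
        )
    h = estimate_homography(record.corners, tray)
    return [rectify_annotation(h, ann) for ann in record.annotations]
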