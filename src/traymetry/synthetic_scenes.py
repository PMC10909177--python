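"""Synthetic tray scenes with known geometry.

Every scene is built on the metric tray plane first — capsule-shaped fish
(a rectangle with semicircular caps along the length axis, so length, area
and hull are unambiguous) with lengths drawn from per-species log-normal
distributions — and then pushed through a known plane-to-plane projective
map into pixel space. The generating map is kept in the scene truth, which
makes the whole metrology pipeline exactly invertible in the noiseless
limit and gives every consumer a controllable oracle.

The camera is modelled directly as the projective map (scale, out-of-plane
tilt, in-plane rotation, principal offset); no 3D pose is decomposed, since
only the homography matters to every downstream consumer. Defaults emulate
a hand-held capture from a similar distance and angle for every tray:
scale 9.5-10.5 px/cm, tilt 5-15 degrees, rotation within +/-10 degrees.
Noise channels — corner-click jitter, polyline jitter, detection dropout,
misclassification and a Beta confidence model — are all separately
switchable; ``SceneConfig.noiseless()`` zeroes them.

Species defaults follow Mediterranean market catches: 13 labels (one
species split by sexual dimorphism), lengths clipped to the 5-83 cm range
overall with a typical fish around 17 cm, and one elongated outlier species
(Sphyraena sphyraena, 25-83 cm) that dominates the upper tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .annotations_io import (
    DetectionInstance,
    FishAnnotation,
    SpeciesCatalog,
    TrayGeometry,
    TrayImageRecord,
    canonicalize_corners,
)
from .errors import PlacementError, ValidationError
from .metrology import Homography

# name, median length (cm), log-sigma, clip range (cm), width/length aspect
DEFAULT_SPECIES_MODELS: tuple[tuple[str, float, float, tuple[float, float], float], ...] = (
    ("Sepia officinalis", 14.0, 0.30, (6.0, 30.0), 0.45),
    ("Symphodus tinca (male)", 20.0, 0.25, (10.0, 35.0), 0.28),
    ("Symphodus tinca (female)", 16.0, 0.25, (8.0, 30.0), 0.28),
    ("Scorpaena porcus", 15.0, 0.25, (8.0, 25.0), 0.30),
    ("Sphyraena sphyraena", 45.0, 0.30, (25.0, 83.0), 0.12),
    ("Mullus barbatus", 14.0, 0.25, (7.0, 25.0), 0.25),
    ("Mullus surmuletus", 16.0, 0.25, (8.0, 28.0), 0.25),
    ("Sparus aurata", 22.0, 0.30, (10.0, 45.0), 0.30),
    ("Dicentrarchus labrax", 28.0, 0.30, (15.0, 55.0), 0.22),
    ("Pagellus erythrinus", 17.0, 0.25, (9.0, 30.0), 0.28),
    ("Diplodus vulgaris", 15.0, 0.25, (8.0, 25.0), 0.32),
    ("Trachurus trachurus", 18.0, 0.25, (9.0, 32.0), 0.20),
    ("Boops boops", 14.0, 0.25, (5.0, 22.0), 0.22),
)

DEFAULT_SPECIES_NAMES = tuple(m[0] for m in DEFAULT_SPECIES_MODELS)

#: overall clip applied on top of per-species clips
GLOBAL_LENGTH_CLIP = (5.0, 83.0)


@dataclass(frozen=True)
class SpeciesLengthModel:
    """Log-normal length model for one species."""

    name: str
    median_cm: float
    sigma_log: float
    clip_cm: tuple[float, float]
    aspect: float  # body width / total length

    def __post_init__(self) -> None:
        lo, hi = self.clip_cm
        if not (0 < lo < hi):
            raise ValidationError(f"bad clip range {self.clip_cm}")
        if not (0 < self.aspect < 1):
            raise ValidationError(f"aspect must be in (0,1), got {self.aspect}")


@dataclass(frozen=True)
class CameraModel:
    """Plane-to-plane projective camera, sampled per tray."""

    scale_px_per_cm: tuple[float, float] = (9.5, 10.5)
    tilt_deg: tuple[float, float] = (5.0, 15.0)
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    offset_px: tuple[float, float] = (0.0, 20.0)
    view_distance_cm: float = 120.0
    margin_px: float = 60.0


@dataclass(frozen=True)
class NoiseModel:
    corner_jitter_px: float = 1.0
    polyline_jitter_px: float = 1.0
    dropout_p: float = 0.10
    misclassify_p: float = 0.05
    confidence_beta: tuple[float, float] = (8.0, 2.0)

    def __post_init__(self) -> None:
        for p in (self.dropout_p, self.misclassify_p):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"probability {p} outside [0, 1]")


@dataclass(frozen=True)
class SceneConfig:
    tray: TrayGeometry = TrayGeometry(60.0, 40.0)
    species: tuple[SpeciesLengthModel, ...] = tuple(
        SpeciesLengthModel(*m) for m in DEFAULT_SPECIES_MODELS
    )
    mixture: tuple[float, ...] | None = None  # None = uniform
    fish_per_tray: tuple[int, int] = (3, 8)
    camera: CameraModel = CameraModel()
    noise: NoiseModel = NoiseModel()

    def __post_init__(self) -> None:
        lo, hi = self.fish_per_tray
        if lo > hi or lo < 0:
            raise ValidationError(f"bad fish_per_tray range {self.fish_per_tray}")
        if self.mixture is not None:
            if len(self.mixture) != len(self.species):
                raise ValidationError("mixture length must match species count")
            if any(w < 0 for w in self.mixture) or sum(self.mixture) <= 0:
                raise ValidationError("mixture weights must be >= 0, sum > 0")

    @property
    def catalog(self) -> SpeciesCatalog:
        return SpeciesCatalog.from_names([m.name for m in self.species])

    def noiseless(self) -> "SceneConfig":
        return replace(self, noise=NoiseModel(
            corner_jitter_px=0.0, polyline_jitter_px=0.0,
            dropout_p=0.0, misclassify_p=0.0,
        ))


@dataclass(frozen=True, eq=False)
class SceneTruth:
    """Oracle channel: the generating map and per-fish metric truth."""

    homography_cm_to_px: np.ndarray
    lengths_cm: tuple[float, ...]
    areas_cm2: tuple[float, ...]
    species_ids: tuple[int, ...]

    @property
    def px_to_cm(self) -> Homography:
        return Homography(np.linalg.inv(self.homography_cm_to_px))


def sample_length(model: SpeciesLengthModel, rng: np.random.Generator) -> float:
    """Draw a length from the clipped log-normal (redraw-truncated)."""
    lo = max(model.clip_cm[0], GLOBAL_LENGTH_CLIP[0])
    hi = min(model.clip_cm[1], GLOBAL_LENGTH_CLIP[1])
    for _ in range(1000):
        val = float(np.exp(rng.normal(math.log(model.median_cm), model.sigma_log)))
        if lo <= val <= hi:
            return val
    return float(np.clip(val, lo, hi))


def _capsule_cm(length: float, aspect: float, n_cap: int = 12) -> np.ndarray:
    """Capsule polygon centred at origin, length axis along +x."""
    width = aspect * length
    r = width / 2.0
    hl = max(length / 2.0 - r, 0.0)
    pts = []
    for t in np.linspace(-math.pi / 2, math.pi / 2, n_cap + 1):
        pts.append((hl + r * math.cos(t), r * math.sin(t)))
    for t in np.linspace(math.pi / 2, 3 * math.pi / 2, n_cap + 1):
        pts.append((-hl + r * math.cos(t), r * math.sin(t)))
    return np.asarray(pts)


def _camera_matrix(scale: float, tilt_rad: float, rot_rad: float,
                   distance_cm: float) -> np.ndarray:
    """cm -> px map before the final translation."""
    tilt = np.array([
        [1.0, 0.0, 0.0],
        [0.0, math.cos(tilt_rad), 0.0],
        [0.0, -math.sin(tilt_rad) / distance_cm, 1.0],
    ])
    scale_m = np.diag([scale, scale, 1.0])
    c, s = math.cos(rot_rad), math.sin(rot_rad)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rot @ scale_m @ tilt


def _place_fish(model: SpeciesLengthModel, tray: TrayGeometry,
                rng: np.random.Generator, max_tries: int = 100,
                max_length_redraws: int = 20
                ) -> tuple[float, float, float, float]:
    """Sample (length, cx, cy, angle) so the capsule stays on the tray."""
    hw, hh = tray.width_cm / 2.0, tray.height_cm / 2.0
    for _ in range(max_length_redraws):
        length = sample_length(model, rng)
        r = model.aspect * length / 2.0
        hl = max(length / 2.0 - r, 0.0)
        for _ in range(max_tries):
            ang = rng.uniform(0.0, math.pi)
            ext_x = hl * abs(math.cos(ang)) + r
            ext_y = hl * abs(math.sin(ang)) + r
            if ext_x > hw or ext_y > hh:
                continue
            cx = rng.uniform(ext_x, tray.width_cm - ext_x)
            cy = rng.uniform(ext_y, tray.height_cm - ext_y)
            return length, cx, cy, ang
    raise PlacementError(
        f"could not place a {model.name} (length ~{length:.1f} cm) on the "
        f"{tray.width_cm}x{tray.height_cm} cm tray"
    )


def generate_scene(config: SceneConfig, seed: int, image_id: int = 0
                   ) -> tuple[TrayImageRecord, SceneTruth, list[DetectionInstance]]:
    """One tray scene: annotations, metric truth and degraded detections.

    Fully deterministic in ``seed``. Fish never exceed the tray bounds, so
    every projected mask lies inside the image canvas.
    """
    rng = np.random.default_rng(seed)
    cam = config.camera
    noise = config.noise
    tray = config.tray

    scale = rng.uniform(*cam.scale_px_per_cm)
    tilt = math.radians(rng.uniform(*cam.tilt_deg))
    rot = math.radians(rng.uniform(*cam.rotation_deg))
    base = _camera_matrix(scale, tilt, rot, cam.view_distance_cm)

    tray_corners_cm = np.asarray(tray.corners_cm)
    hom = np.column_stack([tray_corners_cm, np.ones(4)]) @ base.T
    proj = hom[:, :2] / hom[:, 2:3]
    offset = rng.uniform(*cam.offset_px, size=2)
    shift = cam.margin_px + offset - proj.min(axis=0)
    translate = np.array([[1.0, 0.0, shift[0]], [0.0, 1.0, shift[1]],
                          [0.0, 0.0, 1.0]])
    cm_to_px = translate @ base
    px_corners = proj + shift
    img_w = int(math.ceil(px_corners[:, 0].max() + cam.margin_px))
    img_h = int(math.ceil(px_corners[:, 1].max() + cam.margin_px))

    def project(pts_cm: np.ndarray) -> np.ndarray:
        h = np.column_stack([pts_cm, np.ones(len(pts_cm))]) @ cm_to_px.T
        return h[:, :2] / h[:, 2:3]

    n_fish = int(rng.integers(config.fish_per_tray[0],
                              config.fish_per_tray[1] + 1))
    weights = (np.asarray(config.mixture, float) / sum(config.mixture)
               if config.mixture is not None
               else np.full(len(config.species), 1.0 / len(config.species)))

    annotations: list[FishAnnotation] = []
    lengths: list[float] = []
    areas: list[float] = []
    species_ids: list[int] = []
    for inst_id in range(n_fish):
        sid = int(rng.choice(len(config.species), p=weights))
        model = config.species[sid]
        length, cx, cy, ang = _place_fish(model, tray, rng)
        c, s = math.cos(ang), math.sin(ang)
        rot2 = np.array([[c, -s], [s, c]])
        capsule_cm = _capsule_cm(length, model.aspect) @ rot2.T + (cx, cy)
        centreline_cm = np.array([[-length / 2, 0.0], [0.0, 0.0],
                                  [length / 2, 0.0]]) @ rot2.T + (cx, cy)

        mask_px = project(capsule_cm)
        poly_px = project(centreline_cm)
        if noise.polyline_jitter_px > 0:
            poly_px = poly_px + rng.normal(0.0, noise.polyline_jitter_px,
                                           poly_px.shape)
        x0, y0 = mask_px.min(axis=0)
        x1, y1 = mask_px.max(axis=0)
        import shapely
        annotations.append(FishAnnotation(
            instance_id=inst_id,
            species_id=sid,
            mask=(tuple(map(tuple, mask_px)),),
            bbox=(float(x0), float(y0), float(x1 - x0), float(y1 - y0)),
            size_polyline=tuple(map(tuple, poly_px)),
        ))
        lengths.append(length)
        areas.append(float(shapely.Polygon(capsule_cm).area))
        species_ids.append(sid)

    corner_px = px_corners.copy()
    if noise.corner_jitter_px > 0:
        corner_px = corner_px + rng.normal(0.0, noise.corner_jitter_px,
                                           corner_px.shape)
    record = TrayImageRecord(
        image_id=image_id, width=img_w, height=img_h,
        corners=canonicalize_corners(corner_px),
        annotations=tuple(annotations),
    )
    truth = SceneTruth(
        homography_cm_to_px=cm_to_px,
        lengths_cm=tuple(lengths),
        areas_cm2=tuple(areas),
        species_ids=tuple(species_ids),
    )

    detections: list[DetectionInstance] = []
    n_species = len(config.species)
    for ann in annotations:
        if rng.random() < noise.dropout_p:
            continue
        sid = ann.species_id
        if n_species > 1 and rng.random() < noise.misclassify_p:
            sid = int(rng.choice([i for i in range(n_species) if i != sid]))
        a, b = noise.confidence_beta
        detections.append(DetectionInstance(
            species_id=sid, mask=ann.mask, bbox=ann.bbox,
            confidence=float(rng.beta(a, b)),
        ))
    return record, truth, detections


def generate_dataset(config: SceneConfig, n_trays: int, seed: int
                     ) -> tuple[list[TrayImageRecord], list[SceneTruth],
                                list[list[DetectionInstance]]]:
    """n independent trays; tray i uses the derived seed ``seed + i``."""
    if n_trays < 0:
        raise ValidationError(f"n_trays must be >= 0, got {n_trays}")
    records, truths, dets = [], [], []
    for i in range(n_trays):
        r, t, d = generate_scene(config, seed=seed + i, image_id=i)
        records.append(r)
        truths.append(t)
        dets.append(d)
    return records, truths, dets


def truth_table(truths: Sequence[SceneTruth], catalog: SpeciesCatalog):
    """Flatten scene truths to a pandas frame (one row per fish)."""
    import pandas as pd

    rows = []
    for img_id, t in enumerate(truths):
        for inst, (length, area, sid) in enumerate(
                zip(t.lengths_cm, t.areas_cm2, t.species_ids)):
            rows.append({
                "image_id": img_id, "instance_id": inst,
                "species_id": sid, "species": catalog.name_of(sid),
                "true_length_cm": length, "true_area_cm2": area,
            })
    return pd.DataFrame(rows)
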