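from __future__ import annotations

import numpy as np
import pytest

from traymetry.annotations_io import (
    CornerQuad,
    FishAnnotation,
    DetectionInstance,
    SpeciesCatalog,
    TrayGeometry,
    TrayImageRecord,
)


@pytest.fixture
def tray() -> TrayGeometry:
    return TrayGeometry(60.0, 40.0)


@pytest.fixture
def catalog3() -> SpeciesCatalog:
    return SpeciesCatalog.from_names(["sardine", "bream", "cuttlefish"])


def square_ring(x: float, y: float, side: float):
    return ((x, y), (x + side, y), (x + side, y + side), (x, y + side))


def make_annotation(instance_id=0, species_id=0, x=10.0, y=10.0, side=20.0,
                    polyline=None) -> FishAnnotation:
    ring = square_ring(x, y, side)
    return FishAnnotation(
        instance_id=instance_id, species_id=species_id,
        mask=(ring,), bbox=(x, y, side, side),
        size_polyline=polyline if polyline is not None
        else ((x, y + side / 2), (x + side, y + side / 2)),
    )


def make_detection(species_id=0, x=10.0, y=10.0, side=20.0,
                   confidence=0.9) -> DetectionInstance:
    return DetectionInstance(
        species_id=species_id, mask=(square_ring(x, y, side),),
        bbox=(x, y, side, side), confidence=confidence,
    )


def make_record(image_id=0, width=800, height=600, corners=None,
                annotations=()) -> TrayImageRecord:
    return TrayImageRecord(
        image_id=image_id, width=width, height=height,
        corners=corners, annotations=tuple(annotations),
    )


@pytest.fixture
def unit_quad() -> CornerQuad:
    return CornerQuad(((0.0, 0.0), (60.0, 0.0), (60.0, 40.0), (0.0, 40.0)))
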