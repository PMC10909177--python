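import numpy as np
import pytest

from traymetry.annotations_io import SpeciesCatalog
from traymetry.detection_eval import (
    average_precision,
    confusion_with_fn,
    map_curve,
    mask_iou,
    match_instances,
    per_class_f1,
)
from traymetry.errors import EmptyMaskError, UndefinedAPError, ValidationError

from conftest import make_annotation, make_detection, square_ring
from oracle_utils import ap_bruteforce, greedy_match_naive, raster_iou


def rect_ann(x, y, w, h, species=0, instance_id=0):
    ring = ((x, y), (x + w, y), (x + w, y + h), (x, y + h))
    return make_annotation().__class__(
        instance_id=instance_id, species_id=species, mask=(ring,),
        bbox=(x, y, w, h), size_polyline=((x, y), (x + w, y + h)))


def rect_det(x, y, w, h, species=0, confidence=0.9):
    ring = ((x, y), (x + w, y), (x + w, y + h), (x, y + h))
    return make_detection().__class__(
        species_id=species, mask=(ring,), bbox=(x, y, w, h),
        confidence=confidence)


def rect_iou_exact(a, b):
    """Axis-aligned rectangle IoU by interval arithmetic."""
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union else 0.0


def random_toy_scene(rng, n_classes=3, max_gt=4):
    """Rect ground truths plus jittered/false detections."""
    gts, preds = [], []
    for i in range(int(rng.integers(1, max_gt + 1))):
        x, y = rng.uniform(0, 200, 2)
        w, h = rng.uniform(20, 60, 2)
        sp = int(rng.integers(n_classes))
        gts.append(rect_ann(x, y, w, h, species=sp, instance_id=i))
        if rng.random() < 0.8:  # jittered detection
            dx, dy = rng.uniform(-10, 10, 2)
            sp_d = sp if rng.random() < 0.8 else int(rng.integers(n_classes))
            preds.append(rect_det(x + dx, y + dy, w, h, species=sp_d,
                                  confidence=float(rng.uniform(0.2, 1.0))))
    for _ in range(int(rng.integers(0, 3))):  # false positives
        x, y = rng.uniform(300, 500, 2)
        preds.append(rect_det(x, y, 30, 30, species=int(rng.integers(n_classes)),
                              confidence=float(rng.uniform(0.2, 1.0))))
    return preds, gts


class TestMaskIoU:
    def test_identical_masks(self):
        ring = square_ring(0, 0, 10)
        assert mask_iou((ring,), (ring,)) == pytest.approx(1.0)

    def test_disjoint_masks(self):
        assert mask_iou((square_ring(0, 0, 10),),
                        (square_ring(100, 100, 10),)) == 0.0

    def test_overlapping_rectangles_third(self):
        a = ((0, 0), (10, 0), (10, 10), (0, 10))
        b = ((5, 0), (15, 0), (15, 10), (5, 10))
        assert mask_iou((a,), (b,)) == pytest.approx(1.0 / 3.0)
        assert mask_iou((a,), (b,)) == pytest.approx(
            raster_iou([a], [b], cell=0.05), abs=5e-3)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = square_ring(*rng.uniform(0, 50, 2), rng.uniform(5, 30))
            b = square_ring(*rng.uniform(0, 50, 2), rng.uniform(5, 30))
            assert mask_iou((a,), (b,)) == pytest.approx(mask_iou((b,), (a,)))

    def test_zero_area_mask_rejected(self):
        degenerate = ((0, 0), (10, 0), (5, 0))
        with pytest.raises(EmptyMaskError):
            mask_iou((degenerate,), (square_ring(0, 0, 10),))


class TestMatchInstances:
    def test_exact_match(self):
        gt = [rect_ann(0, 0, 10, 10)]
        pred = [rect_det(0, 0, 10, 10)]
        res = match_instances(pred, gt, 0.5)
        assert res.pairs == ((0, 0, pytest.approx(1.0)),)
        assert res.unmatched_gt == () and res.unmatched_pred == ()

    def test_no_predictions_all_missed(self):
        gts = [rect_ann(i * 30, 0, 10, 10, instance_id=i) for i in range(3)]
        res = match_instances([], gts, 0.5)
        assert res.unmatched_gt == (0, 1, 2)

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValidationError):
            match_instances([], [], 1.0)

    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("class_agnostic", [False, True])
    def test_matches_naive_greedy_oracle(self, seed, class_agnostic):
        rng = np.random.default_rng(100 + seed)
        preds, gts = random_toy_scene(rng)
        iou = [[rect_iou_exact(p.bbox, g.bbox) for g in gts] for p in preds]
        expected = greedy_match_naive(
            [p.confidence for p in preds], iou,
            [p.species_id for p in preds], [g.species_id for g in gts],
            0.5, class_agnostic)
        res = match_instances(preds, gts, 0.5, class_agnostic=class_agnostic)
        assert sorted((pi, gj) for pi, gj, _ in res.pairs) == sorted(expected)


class TestAveragePrecision:
    def test_perfect_detector(self):
        gts = [[rect_ann(0, 0, 10, 10)], [rect_ann(50, 50, 20, 20)]]
        preds = [[rect_det(0, 0, 10, 10)], [rect_det(50, 50, 20, 20)]]
        assert average_precision(preds, gts, 0, 0.5) == pytest.approx(1.0)

    def test_fp_ranked_above_single_tp(self):
        """FP at conf .9 then TP at .8 for 1 gt: precision 0.5 at all recalls."""
        gts = [[rect_ann(0, 0, 10, 10)]]
        preds = [[rect_det(200, 200, 10, 10, confidence=0.9),
                  rect_det(0, 0, 10, 10, confidence=0.8)]]
        assert average_precision(preds, gts, 0, 0.5) == pytest.approx(0.5)

    def test_no_gt_of_class_is_undefined(self):
        with pytest.raises(UndefinedAPError):
            average_precision([[rect_det(0, 0, 10, 10)]],
                              [[rect_ann(0, 0, 10, 10, species=1)]], 0, 0.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_pr_integration(self, seed):
        rng = np.random.default_rng(500 + seed)
        scenes = [random_toy_scene(rng) for _ in range(3)]
        preds_bi = [p for p, _ in scenes]
        gts_bi = [g for _, g in scenes]
        for sp in range(3):
            flags, n_gt = [], 0
            for preds, gts in zip(preds_bi, gts_bi):
                cls_p = [p for p in preds if p.species_id == sp]
                cls_g = [g for g in gts if g.species_id == sp]
                n_gt += len(cls_g)
                iou = [[rect_iou_exact(p.bbox, g.bbox) for g in cls_g]
                       for p in cls_p]
                pairs = greedy_match_naive(
                    [p.confidence for p in cls_p], iou,
                    [0] * len(cls_p), [0] * len(cls_g), 0.5, True)
                matched = {pi for pi, _ in pairs}
                flags.extend((p.confidence, i in matched)
                             for i, p in enumerate(cls_p))
            if n_gt == 0:
                continue
            expected = ap_bruteforce([c for c, _ in flags],
                                     [f for _, f in flags], n_gt)
            assert average_precision(preds_bi, gts_bi, sp, 0.5) == \
                pytest.approx(expected, abs=1e-12)

    def test_duplicating_predictions_never_raises_ap(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            preds, gts = random_toy_scene(rng)
            if not any(g.species_id == 0 for g in gts):
                continue
            base = average_precision([preds], [gts], 0, 0.5)
            dupes = [rect_det(p.bbox[0], p.bbox[1], p.bbox[2], p.bbox[3],
                              species=p.species_id,
                              confidence=p.confidence * 0.5) for p in preds]
            aug = average_precision([preds + dupes], [gts], 0, 0.5)
            assert aug <= base + 1e-12


class TestMapCurve:
    def test_perfect_detector_flat_at_one(self):
        cat = SpeciesCatalog.from_names(["a", "b"])
        gts = [[rect_ann(0, 0, 10, 10, species=0),
                rect_ann(50, 50, 20, 20, species=1)]]
        preds = [[rect_det(0, 0, 10, 10, species=0),
                  rect_det(50, 50, 20, 20, species=1)]]
        curve = map_curve(preds, gts, [0.5, 0.7, 0.9], cat)
        assert all(v == pytest.approx(1.0) for v in curve.values())

    def test_thresholds_must_increase(self):
        cat = SpeciesCatalog.from_names(["a"])
        with pytest.raises(ValidationError):
            map_curve([], [], [0.7, 0.5], cat)

    def test_monotone_non_increasing_on_random_scenes(self):
        cat = SpeciesCatalog.from_names(["a", "b", "c"])
        rng = np.random.default_rng(9)
        scenes = [random_toy_scene(rng) for _ in range(30)]
        curve = map_curve([p for p, _ in scenes], [g for _, g in scenes],
                          [0.5, 0.6, 0.7, 0.8, 0.9], cat)
        vals = list(curve.values())
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


class TestConfusionWithFN:
    def test_all_detected_all_correct(self):
        cat = SpeciesCatalog.from_names(["a", "b"])
        gts = [[rect_ann(0, 0, 10, 10, species=0),
                rect_ann(50, 50, 20, 20, species=1, instance_id=1)]]
        preds = [[rect_det(0, 0, 10, 10, species=0),
                  rect_det(50, 50, 20, 20, species=1)]]
        conf = confusion_with_fn(preds, gts, cat)
        assert np.allclose(conf.matrix[:, :2], 100.0 * np.eye(2))
        assert np.allclose(conf.matrix[:, 2], 0.0)

    def test_nothing_detected_all_fn(self):
        cat = SpeciesCatalog.from_names(["a", "b"])
        gts = [[rect_ann(0, 0, 10, 10, species=0)]]
        conf = confusion_with_fn([[]], gts, cat)
        assert conf.matrix[0, 2] == pytest.approx(100.0)
        assert 1 in conf.empty_rows

    def test_toy_with_misclassification_and_miss(self):
        """2 of species a: one called b, one missed; 1 of b: correct."""
        cat = SpeciesCatalog.from_names(["a", "b"])
        gts = [[rect_ann(0, 0, 10, 10, species=0, instance_id=0),
                rect_ann(100, 0, 10, 10, species=0, instance_id=1),
                rect_ann(200, 0, 10, 10, species=1, instance_id=2)]]
        preds = [[rect_det(0, 0, 10, 10, species=1, confidence=0.9),
                  rect_det(200, 0, 10, 10, species=1, confidence=0.8)]]
        conf = confusion_with_fn(preds, gts, cat)
        assert conf.counts.tolist() == [[0, 1, 1], [0, 1, 0]]
        assert conf.matrix[0].tolist() == pytest.approx([0.0, 50.0, 50.0])
        assert conf.matrix[1].tolist() == pytest.approx([0.0, 100.0, 0.0])

    def test_rows_sum_to_hundred(self):
        cat = SpeciesCatalog.from_names(["a", "b", "c"])
        rng = np.random.default_rng(21)
        scenes = [random_toy_scene(rng) for _ in range(20)]
        conf = confusion_with_fn([p for p, _ in scenes],
                                 [g for _, g in scenes], cat)
        sums = conf.matrix.sum(axis=1)
        for i, s in enumerate(sums):
            if i in conf.empty_rows:
                assert s == 0.0
            else:
                assert s == pytest.approx(100.0, abs=1e-6)


class TestPerClassF1:
    def test_perfect_detector_f1_one(self):
        cat = SpeciesCatalog.from_names(["a"])
        gts = [[rect_ann(0, 0, 10, 10)]]
        preds = [[rect_det(0, 0, 10, 10)]]
        f1 = per_class_f1(preds, gts, cat)
        conf = confusion_with_fn(preds, gts, cat)
        assert f1[0] == 1.0
        assert np.allclose(conf.matrix, [[100.0, 0.0]])

    def test_counts_from_hand_enumeration(self):
        cat = SpeciesCatalog.from_names(["a", "b"])
        # species a: 1 TP, 1 FN; one FP of species a elsewhere
        gts = [[rect_ann(0, 0, 10, 10, species=0, instance_id=0),
                rect_ann(100, 0, 10, 10, species=0, instance_id=1)]]
        preds = [[rect_det(0, 0, 10, 10, species=0, confidence=0.9),
                  rect_det(300, 300, 10, 10, species=0, confidence=0.5)]]
        f1 = per_class_f1(preds, gts, cat)
        assert f1[0] == pytest.approx(2 * 1 / (2 * 1 + 1 + 1))
        assert f1[1] == 0.0
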