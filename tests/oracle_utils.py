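"""Independent oracles used by the test-suite.

These deliberately avoid the code paths they check: areas and IoU come from
dense point-in-polygon counting (matplotlib's even-odd path test, not
shapely), matching from a naive quadratic greedy loop, and AP from explicit
precision-maximization over ranking prefixes.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path as MplPath


def _inside_even_odd(rings, pts: np.ndarray) -> np.ndarray:
    """Even-odd containment: inside an odd number of rings (holes subtract)."""
    inside = np.zeros(len(pts), dtype=int)
    for ring in rings:
        inside += MplPath(np.asarray(ring)).contains_points(pts).astype(int)
    return inside % 2 == 1


def raster_area(rings, cell: float = 0.1) -> float:
    """Polygon area by counting grid-cell centres inside (even-odd rule)."""
    allv = np.vstack([np.asarray(r) for r in rings])
    x0, y0 = allv.min(axis=0) - cell
    x1, y1 = allv.max(axis=0) + cell
    xs = np.arange(x0 + cell / 2, x1, cell)
    ys = np.arange(y0 + cell / 2, y1, cell)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    return float(_inside_even_odd(rings, pts).sum()) * cell * cell


def raster_iou(rings_a, rings_b, cell: float = 0.05) -> float:
    """Mask IoU by pixel-grid counting over the joint bounding box."""
    allv = np.vstack([np.asarray(r) for r in list(rings_a) + list(rings_b)])
    x0, y0 = allv.min(axis=0) - cell
    x1, y1 = allv.max(axis=0) + cell
    xs = np.arange(x0 + cell / 2, x1, cell)
    ys = np.arange(y0 + cell / 2, y1, cell)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_a = _inside_even_odd(rings_a, pts)
    in_b = _inside_even_odd(rings_b, pts)
    union = (in_a | in_b).sum()
    return float((in_a & in_b).sum() / union) if union else 0.0


def greedy_match_naive(pred_confidences, iou_matrix, pred_classes, gt_classes,
                       threshold, class_agnostic):
    """Reference greedy matcher, written as plain nested loops.

    Returns the set of (pred, gt) pairs under the documented rule:
    predictions in descending confidence (ties: lower index), each taking
    its highest-IoU eligible unmatched gt (ties: lower gt index).
    """
    n_pred = len(pred_confidences)
    order = sorted(range(n_pred), key=lambda i: (-pred_confidences[i], i))
    taken = set()
    pairs = []
    for pi in order:
        best, best_iou = None, None
        for gj in range(len(gt_classes)):
            if gj in taken:
                continue
            if not class_agnostic and pred_classes[pi] != gt_classes[gj]:
                continue
            iou = iou_matrix[pi][gj]
            if iou < threshold:
                continue
            if best_iou is None or iou > best_iou:
                best, best_iou = gj, iou
        if best is not None:
            taken.add(best)
            pairs.append((pi, best))
    return pairs


def ap_bruteforce(confidences, is_tp, n_gt) -> float:
    """101-point AP by explicit prefix enumeration of the ranking."""
    order = sorted(range(len(confidences)), key=lambda i: (-confidences[i], i))
    flags = [is_tp[i] for i in order]
    best = []
    for r in np.linspace(0, 1, 101):
        pmax = 0.0
        tp = fp = 0
        for f in flags:
            tp, fp = tp + (1 if f else 0), fp + (0 if f else 1)
            recall = tp / n_gt
            if recall >= r - 1e-12:
                pmax = max(pmax, tp / (tp + fp))
        best.append(pmax)
    return float(np.mean(best))


def camera_like_matrix(rng, scale=(5.0, 15.0), tilt_max=25.0, rot_max=15.0,
                       distance=120.0):
    """Random cm->px projective map from the plausible capture family."""
    import math

    s = rng.uniform(*scale)
    tilt = math.radians(rng.uniform(0.0, tilt_max))
    rot = math.radians(rng.uniform(-rot_max, rot_max))
    tx, ty = rng.uniform(50, 400, 2)
    t = np.array([[1, 0, tx], [0, 1, ty], [0, 0, 1.0]])
    c, si = math.cos(rot), math.sin(rot)
    r = np.array([[c, -si, 0], [si, c, 0], [0, 0, 1.0]])
    k = np.diag([s, s, 1.0])
    p = np.array([[1, 0, 0], [0, math.cos(tilt), 0],
                  [0, -math.sin(tilt) / distance, 1.0]])
    return t @ r @ k @ p


def apply_matrix(m, pts):
    pts = np.atleast_2d(np.asarray(pts, float))
    h = np.column_stack([pts, np.ones(len(pts))]) @ m.T
    return h[:, :2] / h[:, 2:3]


def random_convex_quad(rng: np.random.Generator, spread: float = 100.0):
    """Random strictly-convex quadrilateral (angles on a jittered ellipse)."""
    while True:
        angles = np.sort(rng.uniform(0, 2 * np.pi, 4))
        if np.min(np.diff(angles)) < 0.3:
            continue
        a, b = rng.uniform(0.4 * spread, spread, 2)
        cx, cy = rng.uniform(-spread, spread, 2)
        pts = np.column_stack([cx + a * np.cos(angles), cy + b * np.sin(angles)])
        # strict convexity / non-collinearity check
        ok = True
        for i in range(4):
            p, q, r = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
            cross = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
            if abs(cross) < 1e-3:
                ok = False
        if ok:
            return pts
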