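"""Size regression: features, normalization, cross-validation, prediction.

The regressor learns the pixel-to-centimetre conversion implicitly from
per-instance image features — no calibration is available at inference time.
The feature layout is fixed:

    [bbox_x, bbox_y, bbox_w, bbox_h | mask_area_px | one-hot species | corners?]

where the optional trailing block is the 8 tray-handle corner coordinates
(the calibrated variant, available only for corner-labelled training
images). The bounding box enters as all four of (x, y, w, h): position is
what lets an uncalibrated model absorb perspective. Species enters one-hot
so no artificial order is imposed.

Regressors are a registry of named scikit-learn estimators; gradient-boosted
trees are the default. Evaluation follows a repeated k-fold protocol (10
repeats of 10-fold by default, each repeat reshuffled with a derived seed),
with normalization refitted on every training fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence, Union

import numpy as np

from .annotations_io import CornerQuad, DetectionInstance, FishAnnotation, SpeciesCatalog
from .errors import (
    FitError,
    FoldError,
    LayoutError,
    MetricUndefinedError,
    MissingCalibrationError,
    MissingCoefficientError,
    ValidationError,
)
from .metrology import polygon_area

#: predicted lengths are clipped here — fish lengths are physically positive
PREDICTION_FLOOR_CM = 0.1

NORMALIZATION_SCHEMES = ("none", "standard_input", "minmax_input", "minmax_io")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureLayout:
    """Shape contract between extracted features and fitted models."""

    n_species: int
    include_corners: bool

    @property
    def length(self) -> int:
        return 4 + 1 + self.n_species + (8 if self.include_corners else 0)


@dataclass(frozen=True)
class FeatureVector:
    """Regressor input for one instance (all in pixel units)."""

    bbox: tuple[float, float, float, float]
    mask_area_px: float
    species_onehot: tuple[float, ...]
    corner_coords: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        onehot = tuple(float(v) for v in self.species_onehot)
        if sum(1 for v in onehot if v == 1.0) != 1 or any(
                v not in (0.0, 1.0) for v in onehot):
            raise ValidationError("species_onehot must have exactly one 1")
        if not self.mask_area_px > 0:
            raise ValidationError("mask_area_px must be positive")
        cc = self.corner_coords
        if cc is not None:
            cc = tuple(float(v) for v in cc)
            if len(cc) != 8:
                raise ValidationError("corner_coords must have 8 entries")
        object.__setattr__(self, "species_onehot", onehot)
        object.__setattr__(self, "corner_coords", cc)

    @property
    def layout(self) -> FeatureLayout:
        return FeatureLayout(len(self.species_onehot), self.corner_coords is not None)

    def to_array(self) -> np.ndarray:
        parts = [np.asarray(self.bbox, float),
                 np.asarray([self.mask_area_px], float),
                 np.asarray(self.species_onehot, float)]
        if self.corner_coords is not None:
            parts.append(np.asarray(self.corner_coords, float))
        return np.concatenate(parts)


def extract_features(instance: Union[FishAnnotation, DetectionInstance],
                     catalog: SpeciesCatalog,
                     corners: CornerQuad | None = None,
                     include_corners: bool = False) -> FeatureVector:
    """Build the regressor input X' for one instance.

    ``include_corners=True`` appends the 8 tray-corner pixel coordinates
    (the calibrated variant); it requires ``corners``.
    """
    if instance.species_id not in catalog:
        raise ValidationError(
            f"species id {instance.species_id} not in catalog")
    if include_corners and corners is None:
        raise MissingCalibrationError(
            "include_corners=True but no corner quad supplied")
    onehot = [0.0] * len(catalog)
    onehot[instance.species_id] = 1.0
    cc = None
    if include_corners:
        cc = tuple(float(v) for p in corners.points for v in p)
    return FeatureVector(
        bbox=instance.bbox,
        mask_area_px=polygon_area(instance.mask),
        species_onehot=tuple(onehot),
        corner_coords=cc,
    )


def features_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    if not features:
        raise FitError("empty feature list")
    layouts = {f.layout for f in features}
    if len(layouts) != 1:
        raise LayoutError(f"mixed feature layouts: {layouts}")
    return np.vstack([f.to_array() for f in features])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationSpec:
    """Fitted per-column normalization; 'minmax_io' also scales the target.

    Degenerate columns (zero range / zero std) transform to 0. Parameters
    come from the training fold only; the target transform is invertible so
    metrics are always computed in centimetres.
    """

    scheme: str
    shift: np.ndarray
    scale_inv: np.ndarray
    y_shift: float = 0.0
    y_scale_inv: float = 1.0
    y_range: float = 1.0

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.scheme == "none":
            return np.asarray(x, float)
        return (np.asarray(x, float) - self.shift) * self.scale_inv

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        if self.scheme != "minmax_io":
            return np.asarray(y, float)
        return (np.asarray(y, float) - self.y_shift) * self.y_scale_inv

    def inverse_y(self, y: np.ndarray) -> np.ndarray:
        if self.scheme != "minmax_io":
            return np.asarray(y, float)
        return np.asarray(y, float) * self.y_range + self.y_shift


def fit_normalization(features: np.ndarray, targets: np.ndarray,
                      scheme: str) -> NormalizationSpec:
    """Fit a normalization on training rows (>= 2 required)."""
    if scheme not in NORMALIZATION_SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}")
    x = np.asarray(features, float)
    y = np.asarray(targets, float)
    if x.ndim != 2 or len(x) < 2:
        raise FitError(f"need >= 2 training rows, got {0 if x.ndim != 2 else len(x)}")
    def _safe_inv(span: np.ndarray) -> np.ndarray:
        # zero (or denormally tiny) spans are degenerate: column maps to 0
        with np.errstate(divide="ignore", over="ignore"):
            inv = np.where(span > 0, 1.0 / np.where(span > 0, span, 1.0), 0.0)
        return np.where(np.isfinite(inv), inv, 0.0)

    if scheme == "standard_input":
        shift = x.mean(axis=0)
        return NormalizationSpec(scheme, shift, _safe_inv(x.std(axis=0)))
    if scheme in ("minmax_input", "minmax_io"):
        lo = x.min(axis=0)
        rng = x.max(axis=0) - lo
        scale_inv = _safe_inv(rng)
        if scheme == "minmax_io":
            y_lo = float(y.min())
            y_rng = float(y.max() - y.min())
            return NormalizationSpec(
                scheme, lo, scale_inv,
                y_shift=y_lo,
                y_scale_inv=(1.0 / y_rng) if y_rng > 0 else 0.0,
                y_range=y_rng if y_rng > 0 else 1.0,
            )
        return NormalizationSpec(scheme, lo, scale_inv)
    return NormalizationSpec("none", np.zeros(x.shape[1]), np.ones(x.shape[1]))


# ---------------------------------------------------------------------------
# metrics and reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionReport:
    """MAE/MSE/R2/MAPE with fold dispersion.

    ``dispersion_pooled`` is the std of per-instance absolute errors pooled
    over all out-of-fold predictions; ``dispersion_folds`` is the std across
    fold-mean MAEs. Both are reported because a single "±" is ambiguous.
    """

    mae_cm: float
    mse: float
    r2: float
    mape: float
    fold_mae: tuple[float, ...] = ()
    dispersion_pooled: float = 0.0
    dispersion_folds: float = 0.0

    def __post_init__(self) -> None:
        if self.mse < 0 or self.mape < 0 or self.r2 > 1 + 1e-12:
            raise ValidationError("inconsistent regression metrics")


def compute_metrics(y_true: Sequence[float],
                    y_pred: Sequence[float]) -> RegressionReport:
    """Single-split report: MAE, MSE, MAPE, R2 (see class docs)."""
    yt = np.asarray(y_true, float)
    yp = np.asarray(y_pred, float)
    if yt.shape != yp.shape or yt.size == 0:
        raise MetricUndefinedError("y_true/y_pred must be equal nonzero length")
    if np.any(yt == 0):
        raise MetricUndefinedError("MAPE undefined: zero entry in y_true")
    ss_tot = float(((yt - yt.mean()) ** 2).sum())
    if ss_tot == 0:
        raise MetricUndefinedError("R2 undefined: zero-variance y_true")
    err = yp - yt
    abs_err = np.abs(err)
    return RegressionReport(
        mae_cm=float(abs_err.mean()),
        mse=float((err ** 2).mean()),
        r2=1.0 - float((err ** 2).sum()) / ss_tot,
        mape=float((abs_err / np.abs(yt)).mean()),
        dispersion_pooled=float(abs_err.std()),
    )


# ---------------------------------------------------------------------------
# regressor registry
# ---------------------------------------------------------------------------

def _make_gbr(seed):
    from sklearn.ensemble import GradientBoostingRegressor
    return GradientBoostingRegressor(random_state=seed)


def _make_extra_trees(seed):
    from sklearn.ensemble import ExtraTreesRegressor
    return ExtraTreesRegressor(n_estimators=200, random_state=seed)


def _make_random_forest(seed):
    from sklearn.ensemble import RandomForestRegressor
    return RandomForestRegressor(n_estimators=200, random_state=seed)


def _make_svm_radial(seed):
    from sklearn.svm import SVR
    return SVR(kernel="rbf", C=10.0)


def _make_svm_linear(seed):
    from sklearn.svm import SVR
    return SVR(kernel="linear", C=10.0)


def _make_knn(seed):
    from sklearn.neighbors import KNeighborsRegressor
    return KNeighborsRegressor(n_neighbors=5)


def _make_dummy(seed):
    from sklearn.dummy import DummyRegressor
    return DummyRegressor(strategy="mean")


REGRESSORS: dict[str, Callable[[int], object]] = {
    "gbr": _make_gbr,
    "extra_trees": _make_extra_trees,
    "random_forest": _make_random_forest,
    "svm_radial": _make_svm_radial,
    "svm_linear": _make_svm_linear,
    "knn": _make_knn,
    "dummy": _make_dummy,
}


def _resolve_regressor(spec: str, seed: int):
    if spec not in REGRESSORS:
        raise ValidationError(
            f"unknown regressor {spec!r}; known: {sorted(REGRESSORS)}")
    return REGRESSORS[spec](seed)


# ---------------------------------------------------------------------------
# cross-validation and training
# ---------------------------------------------------------------------------

def kfold_evaluate(features: Sequence[FeatureVector] | np.ndarray,
                   targets: Sequence[float],
                   regressor_spec: str = "gbr",
                   scheme: str = "minmax_input",
                   k: int = 10,
                   repeats: int = 10,
                   base_seed: int = 0) -> RegressionReport:
    """Repeated k-fold evaluation; fully reproducible from ``base_seed``.

    Repeat i reshuffles the rows with seed ``base_seed + i`` and splits into
    k near-equal folds. Normalization is fitted on each training fold only;
    the report pools all out-of-fold predictions over every repeat.
    """
    from sklearn.model_selection import KFold

    x = features if isinstance(features, np.ndarray) else features_matrix(features)
    y = np.asarray(targets, float)
    n = len(y)
    if k > n:
        raise FoldError(f"k={k} exceeds dataset size n={n}")

    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    fold_mae: list[float] = []
    for i in range(repeats):
        seed = base_seed + i
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        for train_idx, val_idx in splitter.split(x):
            norm = fit_normalization(x[train_idx], y[train_idx], scheme)
            model = _resolve_regressor(regressor_spec, seed)
            model.fit(norm.transform(x[train_idx]), norm.transform_y(y[train_idx]))
            pred = norm.inverse_y(np.asarray(model.predict(norm.transform(x[val_idx]))))
            pred = np.maximum(pred, PREDICTION_FLOOR_CM)
            pooled_true.append(y[val_idx])
            pooled_pred.append(pred)
            fold_mae.append(float(np.abs(pred - y[val_idx]).mean()))

    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    base = compute_metrics(yt, yp)
    return RegressionReport(
        mae_cm=base.mae_cm, mse=base.mse, r2=base.r2, mape=base.mape,
        fold_mae=tuple(fold_mae),
        dispersion_pooled=float(np.abs(yp - yt).std()),
        dispersion_folds=float(np.std(fold_mae)),
    )


@dataclass
class SizeRegressor:
    """A fitted size model: estimator + its normalization + feature layout."""

    model: object
    norm: NormalizationSpec
    layout: FeatureLayout
    spec: str


def train_size_regressor(features: Sequence[FeatureVector],
                         targets: Sequence[float],
                         regressor_spec: str = "gbr",
                         scheme: str = "minmax_input",
                         seed: int = 0) -> SizeRegressor:
    """Fit a size regressor on the full training set."""
    x = features_matrix(features)
    y = np.asarray(targets, float)
    if len(y) != len(x) or len(y) == 0:
        raise FitError("features/targets must be equal nonzero length")
    norm = fit_normalization(x, y, scheme)
    model = _resolve_regressor(regressor_spec, seed)
    model.fit(norm.transform(x), norm.transform_y(y))
    return SizeRegressor(model=model, norm=norm,
                         layout=features[0].layout, spec=regressor_spec)


def predict_sizes(model: SizeRegressor,
                  features: Sequence[FeatureVector]) -> np.ndarray:
    """Predict lengths in cm; refuses features with a mismatched layout."""
    if not features:
        return np.empty(0)
    x = features_matrix(features)
    if features[0].layout != model.layout:
        raise LayoutError(
            f"model expects layout {model.layout}, got {features[0].layout}")
    pred = model.norm.inverse_y(np.asarray(model.model.predict(model.norm.transform(x))))
    return np.maximum(pred, PREDICTION_FLOOR_CM)


# ---------------------------------------------------------------------------
# length-to-weight conversion
# ---------------------------------------------------------------------------

def allometric_weight(length_cm: float, species_id: int,
                      coefficients: Mapping[int, tuple[float, float]]) -> float:
    """Allometric biomass W = a * L^b (grams) from species (a, b) table."""
    if species_id not in coefficients:
        raise MissingCoefficientError(
            f"no allometric coefficients for species {species_id}")
    a, b = coefficients[species_id]
    if not a > 0:
        raise ValidationError(f"allometric coefficient a must be > 0, got {a}")
    if not length_cm > 0:
        raise ValidationError(f"length must be > 0, got {length_cm}")
    return float(a * length_cm ** b)
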