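"""Exception hierarchy shared across the package."""


class TraymetryError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TraymetryError):
    """Malformed annotation file; message names the byte offset."""


class ValidationError(TraymetryError):
    """A domain-type invariant was violated."""


class DegenerateQuadError(ValidationError):
    """Corner quad has a collinear triple or is otherwise unusable."""


class MissingCalibrationError(TraymetryError):
    """An operation requiring tray corners was given a record without them."""


class HorizonPointError(TraymetryError):
    """A point maps to (or beyond) the horizon under the homography."""


class InvalidPolylineError(ValidationError):
    """Size polyline has fewer than two vertices."""


class EmptyMaskError(ValidationError):
    """Mask polygon has zero area."""


class LayoutError(TraymetryError):
    """Feature layout does not match what a fitted model expects."""


class FitError(TraymetryError):
    """Normalization or model fitting received an unusable training set."""


class FoldError(TraymetryError):
    """Cross-validation fold count exceeds the dataset size."""


class MetricUndefinedError(TraymetryError):
    """A regression metric is undefined for the given targets."""


class UndefinedAPError(TraymetryError):
    """Average precision is undefined (no ground truth of the class)."""


class MissingCoefficientError(TraymetryError):
    """No allometric (a, b) coefficients for the requested species."""


class InvalidOpError(ValidationError):
    """Augmentation op outside the configured rotation set / translation range."""


class PlacementError(TraymetryError):
    """Synthetic fish could not be placed on the tray within retry bounds."""
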