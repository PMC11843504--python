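"""Linear inter-session correction of multipass arrival-time quantities.

Fluctuations in room conditions (temperature, pressure), instrument swaps and
traveling-wave settings shift periodic drift times and zero-pass times between
sessions, but the shift is affine to very high precision: values measured in
a new session map onto a reference session as ``reference = a * measured + b``
with R^2 typically above 0.9999. The line is fitted on a handful of calibrant
compounds co-measured in both sessions and then applied to every analyte.
``tp``, ``t0`` and ``tn`` each get their own line — they are never pooled.

Lipids and nonlipids follow slightly different lines under the traveling
wave, which two consequences exploited here: calibrants should share the
analytes' class, and the post-correction residual of a feature corrected with
lipid calibrants screens nonlipid contaminants (residual > ~0.7%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

QUANTITIES = ("t0", "tp", "tn")


@dataclass
class CorrectionLine:
    """An affine map aligning one session's values to a reference session."""

    quantity: str
    slope: float
    intercept: float
    r2: float
    calibrant_ids: list = field(default_factory=list)
    calibrant_residuals_pct: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(f"quantity must be one of {QUANTITIES}")
        if self.slope == 0:
            raise ValueError("correction line slope must be nonzero")

    def __call__(self, values):
        return apply_correction(self, values)


@dataclass(frozen=True)
class ScreeningResult:
    """Residual-based class call for one feature."""

    feature_id: object
    residual_pct: float
    class_flag: str  # "in-class" | "out-of-class"

    def __post_init__(self) -> None:
        if self.residual_pct < 0:
            raise ValueError("residual_pct must be non-negative")


class LinearDriftCorrector(BaseEstimator, TransformerMixin):
    """Ordinary-least-squares session correction, scikit-learn style.

    Fit maps measured values (new session) to reference values (database or
    old session): ``reference = slope * measured + intercept``. Calibrant
    counts are small (typically 5-6), so the fit is plain unweighted OLS.

    Parameters
    ----------
    quantity : {"t0", "tp", "tn"}
        Which arrival-time quantity the line corrects. Lines for different
        quantities are fitted separately, never pooled.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted line coefficients (intercept in ms).
    r2_ : float
        Coefficient of determination on the calibrants.
    calibrant_residuals_pct_ : ndarray
        Post-fit residual of each calibrant, percent of its reference value.
    line_ : CorrectionLine
        The fitted line as a plain record.
    """

    def __init__(self, quantity: str = "tp"):
        self.quantity = quantity

    def fit(self, X, y, calibrant_ids: Sequence | None = None):
        measured = _column(X, "X")
        reference = _column(y, "y")
        if measured.shape[0] != reference.shape[0]:
            raise ValueError("X and y must have the same length")
        if measured.shape[0] < 2:
            raise ValueError("need at least 2 calibrant pairs")
        if np.ptp(measured) == 0:
            raise ValueError("degenerate calibrants: all measured values equal")
        if self.quantity not in QUANTITIES:
            raise ValueError(f"quantity must be one of {QUANTITIES}")
        res = stats.linregress(measured, reference)
        if res.slope == 0:
            raise ValueError("degenerate fit: zero slope")
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        r2 = float(res.rvalue**2)
        self.r2_ = 1.0 if not np.isfinite(r2) else r2
        predicted = self.slope_ * measured + self.intercept_
        with np.errstate(divide="ignore", invalid="ignore"):
            self.calibrant_residuals_pct_ = 100.0 * np.abs(predicted - reference) / reference
        self.n_features_in_ = 1
        self.line_ = CorrectionLine(
            quantity=self.quantity,
            slope=self.slope_,
            intercept=self.intercept_,
            r2=self.r2_,
            calibrant_ids=list(calibrant_ids) if calibrant_ids is not None else [],
            calibrant_residuals_pct=self.calibrant_residuals_pct_,
        )
        return self

    def transform(self, X):
        self._check_fitted()
        values = np.asarray(X, dtype=float)
        return self.slope_ * values + self.intercept_

    def inverse_transform(self, X):
        self._check_fitted()
        values = np.asarray(X, dtype=float)
        return (values - self.intercept_) / self.slope_

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise ValueError("LinearDriftCorrector is not fitted")


def _column(values, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr.ravel()
    if arr.ndim != 1:
        raise ValueError(f"{what} must be 1-dimensional (or a single column)")
    return arr


def fit_correction_line(
    pairs: Iterable[tuple[float, float]],
    quantity: str = "tp",
    calibrant_ids: Sequence | None = None,
) -> CorrectionLine:
    """Fit ``reference = slope * measured + intercept`` on calibrant pairs."""
    pairs = list(pairs)
    measured = [p[0] for p in pairs]
    reference = [p[1] for p in pairs]
    est = LinearDriftCorrector(quantity=quantity)
    est.fit(measured, reference, calibrant_ids=calibrant_ids)
    return est.line_


def apply_correction(line: CorrectionLine, values):
    """Apply a fitted line elementwise; input order is preserved."""
    arr = np.asarray(values, dtype=float)
    out = line.slope * arr + line.intercept
    return float(out) if np.isscalar(values) or arr.ndim == 0 else out


def mean_relative_error(values, references) -> float:
    """Mean of ``100 * |value - reference| / reference``, in percent."""
    v = np.asarray(values, dtype=float).ravel()
    r = np.asarray(references, dtype=float).ravel()
    if v.shape != r.shape:
        raise ValueError(f"length mismatch: {v.shape} vs {r.shape}")
    if v.size == 0:
        raise ValueError("empty input")
    if np.any(r == 0):
        raise ValueError("zero reference value")
    return float(np.mean(100.0 * np.abs(v - r) / np.abs(r)))


def screen_by_residual(
    residuals_pct,
    threshold: float = 0.7,
    feature_ids: Sequence | None = None,
) -> list[ScreeningResult]:
    """Flag features whose post-correction residual exceeds ``threshold`` percent.

    The inequality is strict: a residual exactly at the threshold stays
    in-class. With lipid calibrants, out-of-class flags indicate likely
    nonlipid features.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    residuals = np.asarray(residuals_pct, dtype=float).ravel()
    ids = list(feature_ids) if feature_ids is not None else list(range(residuals.size))
    if len(ids) != residuals.size:
        raise ValueError("feature_ids length mismatch")
    return [
        ScreeningResult(
            feature_id=fid,
            residual_pct=float(res),
            class_flag="out-of-class" if res > threshold else "in-class",
        )
        for fid, res in zip(ids, residuals)
    ]


@dataclass
class GroupCorrectionResult:
    """Self-correction of a flagged feature group."""

    line: CorrectionLine
    mre_pct: float


def group_self_correction(
    pairs: Iterable[tuple[float, float]],
    quantity: str = "tp",
    feature_ids: Sequence | None = None,
) -> GroupCorrectionResult:
    """Fit a fresh line *within* a flagged group and report its post-fit MRE.

    High-residual features that share their own affine map (e.g. nonlipids
    corrected with lipid calibrants) self-correct far better than they correct
    through the out-of-class line; comparing this MRE against the original
    line's MRE on the same group confirms or refutes the class split.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 flagged features for self-correction")
    line = fit_correction_line(pairs, quantity=quantity, calibrant_ids=feature_ids)
    measured = np.array([p[0] for p in pairs])
    reference = np.array([p[1] for p in pairs])
    corrected = apply_correction(line, measured)
    return GroupCorrectionResult(line=line, mre_pct=mean_relative_error(corrected, reference))


def warn_on_cross_class(calibrant_classes: Iterable[str], analyte_classes: Iterable[str]) -> None:
    """Warn when lipid analytes are corrected with exclusively nonlipid calibrants.

    Lipids follow a slightly different correction line under the traveling
    wave than other molecule classes, so same-class calibrants are
    recommended; cross-class correction is permitted but less accurate.
    """
    cal = set(calibrant_classes)
    ana = set(analyte_classes)
    if "lipid" in ana and cal and "lipid" not in cal:
        warnings.warn(
            "correcting lipid analytes with nonlipid calibrants; lipid "
            "calibrants are recommended for lipid analytes",
            stacklevel=2,
        )
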