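"""Calibration of visually estimated fecal volumes against EDC.

Years for which scats were scored only in the field (visual percent
fecal volume, vFV) can be folded into corrected-content comparisons by
regressing EDC on vFV through the origin, per category, on the years for
which both are available, and rescaling the visual profiles by the
fitted slopes. The estimator follows the scikit-learn fit/transform
protocol so it composes with pipelines and model selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diet import DegenerateInputError, DietProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationModel:
    """Per-category through-origin slopes and the pair counts behind them.

    Categories with no pairs pass through with slope exactly 1.
    """

    slopes: dict
    n_pairs: dict


class ThroughOriginCalibrator:
    """Per-category regression through the origin of EDC on vFV.

    For each category c the slope is the through-origin least-squares
    estimate ``sum(x*y) / sum(x**2)`` over the supplied (vFV, EDC) pairs.
    Categories never seen in fitting, or seen only with all-zero vFV,
    fall back to slope 1 (pass-through).

    Attributes (after ``fit``)
    --------------------------
    slopes_ : dict category -> slope
    n_pairs_ : dict category -> number of pairs used
    """

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "ThroughOriginCalibrator":
        if params:
            raise ValueError(f"unknown parameters {sorted(params)}")
        return self

    def fit(self, X, y=None) -> "ThroughOriginCalibrator":
        """Fit per-category slopes.

        Parameters
        ----------
        X : DataFrame of vFV values (rows = paired observations,
            columns = categories) or a sequence of category->value dicts.
        y : matching DataFrame/sequence of EDC values.
        """
        X = _as_frame(X)
        y = _as_frame(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of pairs")
        slopes, n_pairs = {}, {}
        for cat in sorted(set(X.columns) | set(y.columns)):
            xv = X[cat].to_numpy(float) if cat in X.columns else np.zeros(len(X))
            yv = y[cat].to_numpy(float) if cat in y.columns else np.zeros(len(y))
            n_pairs[cat] = int(len(xv))
            sxx = float(xv @ xv)
            if sxx == 0.0:
                logger.warning("category %s: all vFV zero; slope set to 1", cat)
                slopes[cat] = 1.0
            else:
                slopes[cat] = float(xv @ yv) / sxx
        self.slopes_ = slopes
        self.n_pairs_ = n_pairs
        return self

    def transform(self, X):
        """Rescale category vFV profiles by the slopes and renormalize to 100.

        Accepts a DietProfile (returns a DietProfile on basis ``edc``) or
        a DataFrame of category values (returns a DataFrame).
        """
        model = self.model_
        if isinstance(X, DietProfile):
            return apply_calibration(X, model)
        X = _as_frame(X)
        out = X.copy().astype(float)
        for cat in out.columns:
            out[cat] = out[cat] * model.slopes.get(cat, 1.0)
        totals = out.sum(axis=1)
        if (totals <= 0).any():
            raise DegenerateInputError("a calibrated profile has zero total")
        return out.div(totals, axis=0) * 100.0

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    @property
    def model_(self) -> CalibrationModel:
        if not hasattr(self, "slopes_"):
            raise AttributeError("calibrator is not fitted")
        return CalibrationModel(slopes=dict(self.slopes_), n_pairs=dict(self.n_pairs_))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.fillna(0.0)
    return pd.DataFrame(list(X)).fillna(0.0)


def fit_vfv_calibration(pairs) -> CalibrationModel:
    """Functional wrapper: fit from (vFV profile, EDC profile) pairs.

    ``pairs`` is a sequence of 2-tuples of category-level DietProfiles
    (or plain dicts).
    """
    if not pairs:
        raise ValueError("need at least one calibration pair")
    xs, ys = [], []
    for x, y in pairs:
        xs.append(x.values if isinstance(x, DietProfile) else x)
        ys.append(y.values if isinstance(y, DietProfile) else y)
    return ThroughOriginCalibrator().fit(xs, ys).model_


def apply_calibration(profile: DietProfile, model: CalibrationModel) -> DietProfile:
    """Slope-rescale a category vFV profile and renormalize to sum 100."""
    if profile.level != "category":
        raise ValueError("calibration applies to category-level profiles")
    scaled = {c: v * model.slopes.get(c, 1.0) for c, v in profile.values.items()}
    total = sum(scaled.values())
    if total <= 0:
        raise DegenerateInputError("all calibrated values are zero")
    values = {c: 100.0 * v / total for c, v in scaled.items()}
    return DietProfile(basis="edc", level="category", values=values)
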