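"""Smoothing-spline curve description and geometric parameter extraction.

A cubic smoothing spline (generalized cross-validation choosing the
penalty by default) is fitted to each respiration curve.  The four shape
parameters are then read off the fitted function:

* ``A``   -- maximum of the fitted spline,
* ``mu``  -- maximum of its first derivative, attained at time ``t_mu``
  with fitted value ``y_mu``,
* ``lambda`` -- x-intercept of the tangent at the steepest point:
  ``y_mu = mu * (t_mu - lambda)``  =>  ``lambda = t_mu - y_mu / mu``,
* ``AUC`` -- trapezoidal integral of the fitted spline over the observed
  time range.

Unlike parametric sigmoids, the spline has no convergence failure mode on
finite data: every curve -- flat, biphasic, artifact-laden -- yields
parameters.  The price is paid on (near-)flat curves, where the smoothed
derivative is dominated by noise and ``lambda``/``mu`` become unreliable
(flagged, and visible downstream as very broad bootstrap intervals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.interpolate import BSpline, CubicSpline, make_smoothing_spline
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import OMNILOG_CAP, CurveParameters, KineticCurve

__all__ = ["SplineFitResult", "fit_spline", "spline_parameters", "SplineFitter"]

#: Below this derivative ceiling (units/hour) a curve is considered to have
#: no identifiable ascent and its lag estimate is flagged unreliable.
MU_FLOOR = 1e-8

#: Evaluation density for derivative maximization, relative to the
#: observation grid.
DENSE_FACTOR = 10


@dataclass
class SplineFitResult:
    """A fitted spline plus everything needed to extract parameters."""

    spline: Union[BSpline, CubicSpline]
    times: np.ndarray          # observation grid (NaN-cleaned)
    values: np.ndarray
    fitted: np.ndarray         # spline on the observation grid
    dense_times: np.ndarray
    dense_fitted: np.ndarray
    dense_slope: np.ndarray
    smoothing: Optional[float]  # None = GCV default
    interpolating: bool = False

    @property
    def residuals(self) -> np.ndarray:
        return self.values - self.fitted


def fit_spline(
    curve: KineticCurve, smoothing: Union[str, float, None] = "auto"
) -> SplineFitResult:
    """Fit a cubic smoothing spline to one curve.

    ``smoothing="auto"`` selects the penalty by generalized
    cross-validation; a float fixes it.  Curves of exactly 4 points get a
    natural interpolating cubic (no smoothing).  Fewer than 4 points is the
    only failure mode and raises ``ValueError``.
    """
    clean = curve.dropna()  # raises for < 4 finite points
    t, v = clean.times, clean.values
    lam = None if smoothing in (None, "auto") else float(smoothing)
    if t.size == 4:
        spl: Union[BSpline, CubicSpline] = CubicSpline(t, v, bc_type="natural")
        interpolating = True
    else:
        spl = make_smoothing_spline(t, v, lam=lam)
        interpolating = False
    dense = np.linspace(t[0], t[-1], DENSE_FACTOR * t.size)
    return SplineFitResult(
        spline=spl,
        times=t,
        values=v,
        fitted=np.asarray(spl(t), dtype=float),
        dense_times=dense,
        dense_fitted=np.asarray(spl(dense), dtype=float),
        dense_slope=np.asarray(spl.derivative()(dense), dtype=float),
        smoothing=lam,
        interpolating=interpolating,
    )


def spline_parameters(
    fit: SplineFitResult, span: Optional[tuple] = None, auc_from_raw: bool = False
) -> CurveParameters:
    """Extract (lambda, mu, A, AUC) from a fitted spline.

    The derivative is maximized on the dense grid with earliest-argmax
    tie-breaking.  Negative lag values are preserved and flagged, never
    clamped.  ``span=(t_lo, t_hi)`` overrides the evaluation window (used
    by the bootstrap so every resample is measured over the original time
    range).  ``auc_from_raw`` integrates the raw observations instead of
    the fitted spline.
    """
    if span is None:
        dense = fit.dense_times
        dense_fitted = fit.dense_fitted
        dense_slope = fit.dense_slope
    else:
        dense = np.linspace(span[0], span[1], DENSE_FACTOR * fit.times.size)
        dense_fitted = np.asarray(fit.spline(dense), dtype=float)
        dense_slope = np.asarray(fit.spline.derivative()(dense), dtype=float)
    A = float(np.max(dense_fitted))
    i_mu = int(np.argmax(dense_slope))  # argmax returns the earliest maximum
    mu = float(dense_slope[i_mu])
    t_mu = float(dense[i_mu])
    y_mu = float(dense_fitted[i_mu])
    if auc_from_raw:
        auc = float(np.trapezoid(fit.values, fit.times))
    else:
        auc = float(np.trapezoid(dense_fitted, dense))
    flags = []
    if mu <= MU_FLOOR:
        lam = math.nan
        flags.append("lambda_unreliable")
    else:
        lam = t_mu - y_mu / mu
        if lam < 0:
            flags.append("lambda_negative")
    if A > OMNILOG_CAP:
        flags.append("A_above_cap")
    return CurveParameters(
        lambda_=lam, mu=mu, A=A, auc=auc, method="spline", flags=tuple(flags)
    )


class SplineFitter(BaseEstimator, RegressorMixin):
    """Sklearn-style smoothing-spline estimator for one curve.

    Parameters
    ----------
    smoothing : "auto" or float, default="auto"
        GCV-selected penalty, or an explicit value.

    Attributes
    ----------
    fit_result_ : SplineFitResult
    lambda_, mu_, A_, auc_ : float
    t_mu_, y_mu_ : float
        Location and fitted value of the steepest point.
    params_ : CurveParameters
    """

    def __init__(self, smoothing: Union[str, float, None] = "auto"):
        self.smoothing = smoothing

    def fit(self, X, y):
        """Fit with times ``X`` (n or n x 1, hours) and values ``y``."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single time column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        from .core import WellCoordinate

        curve = KineticCurve(times=X, values=y, well=WellCoordinate("A", 1))
        self.fit_result_ = fit_spline(curve, smoothing=self.smoothing)
        self.params_ = spline_parameters(self.fit_result_)
        self.lambda_ = self.params_.lambda_
        self.mu_ = self.params_.mu
        self.A_ = self.params_.A
        self.auc_ = self.params_.auc
        i_mu = int(np.argmax(self.fit_result_.dense_slope))
        self.t_mu_ = float(self.fit_result_.dense_times[i_mu])
        self.y_mu_ = float(self.fit_result_.dense_fitted[i_mu])
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_result_")
        X = np.asarray(X, dtype=float)
        flat = X[:, 0] if X.ndim == 2 else X
        return np.asarray(self.fit_result_.spline(flat), dtype=float)
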