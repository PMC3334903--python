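"""Re-implementation of the native OmniLog parametric curve algorithm.

The instrument software derives its parameters from a handful of order
statistics and threshold crossings of the raw readings, with no model and
no interpolation:

* ``MaxHeight`` -- the value at the 10th-percentile-from-the-top rank
  among all readings (read here as the nearest-rank 90th percentile; the
  alternative literal reading "the 10th-highest reading" is available via
  ``max_height_rule="tenth_highest"``).
* ``MinHeight`` -- the 12th smallest value among the first 48 readings.
* ``MidHeight`` -- midway between MinHeight and MaxHeight.
* ``MidTime`` -- the first time a reading strictly exceeds MidHeight.
* ``x% Time`` -- the first time a reading exceeds the value x% of the way
  from MinHeight to MaxHeight.
* ``Slope`` -- total rise over the readings between 15% Time and one
  sample before MidTime, plus total rise between one sample after MidTime
  and 85% Time, divided by (85% Time - 15% Time).
* ``lag = MidTime - (MidHeight - MinHeight) / Slope``.
* ``AUC`` -- the plain sum of all readings (a step-function convention;
  units are OmniLog-unit x reads, not unit x hours, and the value
  overestimates a trapezoidal integral for steep curves).

Only point estimates are produced; the native method has no notion of a
confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .core import CurveParameters, KineticCurve

__all__ = [
    "NativeIntermediates",
    "native_parameters",
    "native_slope",
    "native_auc",
    "NativeOmniLogFitter",
]

#: Readings used for the MinHeight order statistic.
_FIRST_READS = 48
_MIN_RANK = 12  # 12th smallest


@dataclass
class NativeIntermediates:
    """Order statistics and threshold crossings behind the native formulas.

    Indices are sample indices into the curve; ``None`` where the quantity
    is undefined (e.g. a flat curve never crosses MidHeight).
    """

    max_height: float
    min_height: float
    mid_height: float
    mid_index: Optional[int]
    mid_time: Optional[float]
    pct15_index: Optional[int]
    pct15_time: Optional[float]
    pct85_index: Optional[int]
    pct85_time: Optional[float]
    slope: float  # NaN when undefined
    flags: tuple = ()


def _first_exceeding(values: np.ndarray, threshold: float) -> Optional[int]:
    """Index of the first reading strictly above ``threshold`` (no interpolation)."""
    above = np.nonzero(values > threshold)[0]
    return int(above[0]) if above.size else None


def _max_height(values: np.ndarray, rule: str) -> float:
    s = np.sort(values)
    n = s.size
    if rule == "nearest_rank":
        # nearest-rank 90th percentile == 10th percentile counting from the top
        idx = math.ceil(0.9 * n) - 1
        return float(s[idx])
    if rule == "tenth_highest":
        return float(s[-10]) if n >= 10 else float(s[0])
    raise ValueError(f"unknown max_height_rule {rule!r}")


def native_slope(
    curve: KineticCurve, inter: NativeIntermediates
) -> Tuple[float, tuple]:
    """The native slope given the threshold-crossing intermediates.

    Returns ``(slope, flags)``; slope is NaN when 15%/85% Time coincide or
    MidTime is undefined.
    """
    v = curve.values
    t = curve.times
    if inter.mid_index is None or inter.pct15_index is None or inter.pct85_index is None:
        return math.nan, ("slope_undefined",)
    i15, imid, i85 = inter.pct15_index, inter.mid_index, inter.pct85_index
    run = t[i85] - t[i15]
    if run == 0:
        return math.nan, ("slope_undefined",)
    rise = 0.0
    if imid - 1 > i15:
        rise += float(v[imid - 1] - v[i15])
    if i85 > imid + 1:
        rise += float(v[i85] - v[imid + 1])
    return rise / float(run), ()


def native_auc(curve: KineticCurve) -> float:
    """Sum of all readings -- the native step-function 'area under the curve'."""
    return float(np.sum(curve.values))


def native_parameters(
    curve: KineticCurve, max_height_rule: str = "nearest_rank"
) -> Tuple[CurveParameters, NativeIntermediates]:
    """Run the full native algorithm on one curve.

    A curve that never exceeds MidHeight (flat curve) gets NaN lag and
    slope with flags, while A and AUC are still returned.  Curves shorter
    than 48 readings use all available readings for MinHeight and are
    flagged ``short_series``.
    """
    clean = curve.dropna()
    v = clean.values
    t = clean.times
    flags = []

    max_h = _max_height(v, max_height_rule)
    first = v[:_FIRST_READS]
    if first.size < _FIRST_READS:
        flags.append("short_series")
    rank = min(_MIN_RANK, first.size)
    min_h = float(np.sort(first)[rank - 1])
    mid_h = (min_h + max_h) / 2.0

    i_mid = _first_exceeding(v, mid_h)
    thr15 = min_h + 0.15 * (max_h - min_h)
    thr85 = min_h + 0.85 * (max_h - min_h)
    i15 = _first_exceeding(v, thr15)
    i85 = _first_exceeding(v, thr85)

    inter = NativeIntermediates(
        max_height=max_h,
        min_height=min_h,
        mid_height=mid_h,
        mid_index=i_mid,
        mid_time=float(t[i_mid]) if i_mid is not None else None,
        pct15_index=i15,
        pct15_time=float(t[i15]) if i15 is not None else None,
        pct85_index=i85,
        pct85_time=float(t[i85]) if i85 is not None else None,
        slope=math.nan,
    )

    slope, slope_flags = native_slope(clean, inter)
    inter.slope = slope
    flags.extend(slope_flags)

    if i_mid is None:
        flags.append("midtime_undefined")
        lam = math.nan
    elif not math.isfinite(slope) or slope == 0.0:
        lam = math.nan
        if "slope_undefined" not in flags:
            flags.append("slope_undefined")
    else:
        lam = float(t[i_mid]) - (mid_h - min_h) / slope
        if lam < 0:
            flags.append("lambda_negative")

    inter.flags = tuple(flags)
    params = CurveParameters(
        lambda_=lam,
        mu=slope,
        A=max_h,
        auc=native_auc(clean),
        method="native",
        flags=tuple(flags),
    )
    return params, inter


class NativeOmniLogFitter(BaseEstimator):
    """Sklearn-style wrapper around the native instrument algorithm.

    Parameters
    ----------
    max_height_rule : {"nearest_rank", "tenth_highest"}
        Reading of the "10th percentile highest value" phrase.

    Attributes
    ----------
    lambda_, mu_, A_, auc_ : float
    params_ : CurveParameters
    intermediates_ : NativeIntermediates
    """

    def __init__(self, max_height_rule: str = "nearest_rank"):
        self.max_height_rule = max_height_rule

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single time column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        from .core import WellCoordinate

        curve = KineticCurve(times=X, values=y, well=WellCoordinate("A", 1))
        self.params_, self.intermediates_ = native_parameters(
            curve, max_height_rule=self.max_height_rule
        )
        self.lambda_ = self.params_.lambda_
        self.mu_ = self.params_.mu
        self.A_ = self.params_.A
        self.auc_ = self.params_.auc
        return self
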