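"""Parametric growth-model fitting with AIC model selection.

Four classical sigmoid models are fitted to each respiration curve by
nonlinear least squares, in the re-parameterization where the maximum
height ``A``, the maximum slope ``mu`` and the lag phase ``lambda`` appear
directly as model parameters (Zwietering-style forms):

logistic      y = A / (1 + exp(4*mu/A * (lambda - t) + 2))
gompertz      y = A * exp(-exp(mu*e/A * (lambda - t) + 1))
gompertz_exp  gompertz + A * exp(alpha * (t - t_shift))   (secondary ascent)
richards      y = A * (1 + nu * exp(1+nu) *
                       exp(mu/A * (1+nu)**(1 + 1/nu) * (lambda - t)))**(-1/nu)

Richards reduces to the logistic at nu = 1 and approaches Gompertz as
nu -> 0.  The best model is the one minimizing the Gaussian least-squares
AIC, ``n*ln(RSS/n) + 2*(p+1)``; ties go to the model with fewer
parameters, then to the fixed order above.

Biologically implausible estimates (lambda < 0, A > 400 OmniLog units) are
*kept* and flagged -- they are informative about the data (near-flat
drifting wells typically produce the former) and are counted separately in
reliability summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import OMNILOG_CAP, CurveParameters, KineticCurve

__all__ = [
    "MODEL_NAMES",
    "MODEL_PARAM_NAMES",
    "GrowthModelSpec",
    "ModelFitResult",
    "evaluate_model",
    "fit_model",
    "select_best_model",
    "aic",
    "GrowthModelFitter",
]

#: Fixed model order; also the tie-break order for AIC selection.
MODEL_NAMES = ("logistic", "gompertz", "gompertz_exp", "richards")

MODEL_PARAM_NAMES: Dict[str, Tuple[str, ...]] = {
    "logistic": ("A", "mu", "lambda"),
    "gompertz": ("A", "mu", "lambda"),
    "gompertz_exp": ("A", "mu", "lambda", "alpha", "t_shift"),
    "richards": ("A", "mu", "lambda", "nu"),
}

_E = math.e
_EXP_CLIP = 700.0  # exp() overflow guard


@dataclass(frozen=True)
class GrowthModelSpec:
    """A named model with a full parameter vector."""

    name: str
    params: Dict[str, float]

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        expected = MODEL_PARAM_NAMES[self.name]
        missing = set(expected) - set(self.params)
        if missing:
            raise ValueError(f"{self.name} lacks parameters {sorted(missing)}")

    @property
    def theta(self) -> np.ndarray:
        return np.array([self.params[k] for k in MODEL_PARAM_NAMES[self.name]])


def _exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP))


def _eval(name: str, theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    if name == "logistic":
        A, mu, lam = theta
        return A / (1.0 + _exp(4.0 * mu / A * (lam - t) + 2.0))
    if name == "gompertz":
        A, mu, lam = theta
        return A * _exp(-_exp(mu * _E / A * (lam - t) + 1.0))
    if name == "gompertz_exp":
        A, mu, lam, alpha, t_shift = theta
        base = A * _exp(-_exp(mu * _E / A * (lam - t) + 1.0))
        return base + A * _exp(alpha * (t - t_shift))
    if name == "richards":
        A, mu, lam, nu = theta
        inner = nu * _exp(1.0 + nu) * _exp(mu / A * (1.0 + nu) ** (1.0 + 1.0 / nu) * (lam - t))
        return A * (1.0 + inner) ** (-1.0 / nu)
    raise ValueError(f"unknown model {name!r}")


def evaluate_model(spec: Union[GrowthModelSpec, str], t, params: Optional[dict] = None) -> np.ndarray:
    """Evaluate a growth model at times ``t`` (hours).

    Accepts either a :class:`GrowthModelSpec` or ``(name, params)``.
    """
    if isinstance(spec, str):
        spec = GrowthModelSpec(spec, dict(params or {}))
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    theta = spec.theta
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite model parameter")
    return _eval(spec.name, theta, t)


def aic(n: int, rss: float, n_params: int) -> float:
    """Gaussian least-squares AIC: ``n*ln(RSS/n) + 2*(p+1)``."""
    rss = max(float(rss), 1e-300)
    return n * math.log(rss / n) + 2.0 * (n_params + 1)


@dataclass
class ModelFitResult:
    """Outcome of fitting one model to one curve."""

    name: str
    spec: Optional[GrowthModelSpec]
    rss: float
    n: int
    n_params: int
    aic: float
    converged: bool
    parameters: Optional[CurveParameters]
    message: str = ""


def _initial_values(name: str, t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Heuristic, reproducible starting values shared by all models."""
    A0 = max(float(np.max(v)), 1e-3)
    dt = np.diff(t)
    keep = np.nonzero(dt > 0)[0]  # tied resampled times carry no slope information
    dq = (v[keep + 1] - v[keep]) / dt[keep]
    i_star = int(keep[np.argmax(dq)])
    mu0 = max(float(np.max(dq)), 1e-3)
    lam0 = float(t[i_star] - v[i_star] / mu0)
    init = {"A": A0, "mu": mu0, "lambda": lam0, "nu": 1.0, "alpha": 0.01, "t_shift": float(t[-1])}
    return np.array([init[k] for k in MODEL_PARAM_NAMES[name]])


def _bounds(name: str, t: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    t_span = float(t[-1] - t[0])
    lo = {"A": 1e-6, "mu": 1e-6, "lambda": float(t[0]) - 5.0 * t_span,
          "nu": 0.05, "alpha": 1e-6, "t_shift": float(t[0])}
    hi = {"A": 25.0 * OMNILOG_CAP, "mu": np.inf, "lambda": float(t[-1]) + t_span,
          "nu": 20.0, "alpha": 10.0, "t_shift": float(t[-1])}
    names = MODEL_PARAM_NAMES[name]
    return (np.array([lo[k] for k in names]), np.array([hi[k] for k in names]))


def fit_model(curve: KineticCurve, name: str, max_nfev: int = 400) -> ModelFitResult:
    """Fit one named model to a curve by bounded nonlinear least squares.

    Convergence failure is reported via ``converged=False``, never as an
    exception.  A curve with no dynamic range (all readings identical)
    cannot identify any sigmoid's parameters and is reported unfittable,
    matching the behavior of modeling approaches on non-respiring wells.
    """
    try:
        clean = curve.dropna()
    except ValueError as exc:
        n_params = len(MODEL_PARAM_NAMES.get(name, ()))
        return ModelFitResult(name, None, math.nan, 0, n_params, math.inf, False, None, str(exc))
    return fit_model_arrays(clean.times, clean.values, name, max_nfev=max_nfev)


def fit_model_arrays(
    t: np.ndarray, v: np.ndarray, name: str, max_nfev: int = 400
) -> ModelFitResult:
    """Array-level model fit; tolerates tied time points (bootstrap resamples)."""
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}")
    n_params = len(MODEL_PARAM_NAMES[name])
    order = np.argsort(t, kind="stable")
    t, v = np.asarray(t, float)[order], np.asarray(v, float)[order]
    n = t.size
    if n < n_params + 2:
        return ModelFitResult(
            name, None, math.nan, n, n_params, math.inf, False, None, "too few points"
        )
    if np.ptp(v) == 0.0 or np.ptp(t) == 0.0:
        return ModelFitResult(
            name, None, math.nan, n, n_params, math.inf, False, None, "no dynamic range"
        )

    theta0 = _initial_values(name, t, v)
    lo, hi = _bounds(name, t)
    theta0 = np.clip(theta0, lo, hi)

    def resid(theta: np.ndarray) -> np.ndarray:
        return _eval(name, theta, t) - v

    try:
        res = least_squares(resid, theta0, bounds=(lo, hi), max_nfev=max_nfev, method="trf")
    except Exception as exc:  # numerical breakdown inside the solver
        return ModelFitResult(name, None, math.nan, n, n_params, math.inf, False, None, str(exc))

    ok = bool(res.success) and np.all(np.isfinite(res.x)) and np.isfinite(res.cost)
    if ok:
        # require an invertible normal matrix: a flat likelihood means the
        # parameters are not identified by the data
        jtj = res.jac.T @ res.jac
        ok = np.all(np.isfinite(jtj)) and np.linalg.matrix_rank(jtj) == n_params
    if not ok:
        return ModelFitResult(
            name, None, math.nan, n, n_params, math.inf, False, None, res.message if hasattr(res, "message") else ""
        )

    theta = res.x
    rss = float(2.0 * res.cost)
    spec = GrowthModelSpec(name, dict(zip(MODEL_PARAM_NAMES[name], theta.tolist())))
    fitted = _eval(name, theta, t)
    auc = float(np.trapezoid(fitted, t))
    flags = []
    if spec.params["lambda"] < 0:
        flags.append("lambda_negative")
    if spec.params["A"] > OMNILOG_CAP:
        flags.append("A_above_cap")
    params = CurveParameters(
        lambda_=spec.params["lambda"],
        mu=spec.params["mu"],
        A=spec.params["A"],
        auc=auc,
        method="model",
        model_name=name,
        flags=tuple(flags),
    )
    return ModelFitResult(name, spec, rss, n, n_params, aic(n, rss, n_params), True, params)


def select_best_model(
    curve: KineticCurve, names: Sequence[str] = MODEL_NAMES, max_nfev: int = 400
) -> Tuple[ModelFitResult, List[ModelFitResult]]:
    """Fit every requested model and pick the AIC-best converged one.

    Returns ``(best, all_results)``.  If no model converges, ``best`` has
    ``converged=False`` (the curve is "without fittable models").
    """
    results = [fit_model(curve, name, max_nfev=max_nfev) for name in names]
    converged = [r for r in results if r.converged]
    if not converged:
        best = ModelFitResult(
            "none", None, math.nan, len(curve), 0, math.inf, False, None, "no model converged"
        )
        return best, results
    order = {name: i for i, name in enumerate(MODEL_NAMES)}
    best = min(converged, key=lambda r: (r.aic, r.n_params, order.get(r.name, 99)))
    return best, results


class GrowthModelFitter(BaseEstimator, RegressorMixin):
    """Sklearn-style estimator fitting growth models to one curve.

    Parameters
    ----------
    model : str, default="auto"
        One of ``logistic, gompertz, gompertz_exp, richards``, or
        ``"auto"`` to fit all four and select by AIC.
    max_nfev : int, default=400
        Iteration cap for the least-squares solver.

    Attributes
    ----------
    model_name_ : str
        Name of the (selected) model.
    lambda_, mu_, A_, auc_ : float
        Curve parameters of the best fit.
    result_ : ModelFitResult
        Full fit record of the best model.
    aic_table_ : list of ModelFitResult
        Per-model results (only when ``model="auto"``).
    converged_ : bool
    """

    def __init__(self, model: str = "auto", max_nfev: int = 400):
        self.model = model
        self.max_nfev = max_nfev

    def _to_curve(self, X, y) -> KineticCurve:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single time column")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        from .core import WellCoordinate

        return KineticCurve(times=X, values=y, well=WellCoordinate("A", 1))

    def fit(self, X, y):
        """Fit with times ``X`` (n or n x 1, hours) and values ``y``."""
        curve = self._to_curve(X, y)
        if self.model == "auto":
            best, table = select_best_model(curve, max_nfev=self.max_nfev)
            self.aic_table_ = table
        else:
            best = fit_model(curve, self.model, max_nfev=self.max_nfev)
            self.aic_table_ = [best]
        self.result_ = best
        self.converged_ = best.converged
        self.model_name_ = best.name
        if best.converged:
            assert best.parameters is not None
            self.lambda_ = best.parameters.lambda_
            self.mu_ = best.parameters.mu
            self.A_ = best.parameters.A
            self.auc_ = best.parameters.auc
        else:
            self.lambda_ = self.mu_ = self.A_ = self.auc_ = math.nan
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        if not self.converged_:
            raise ValueError("no converged model to predict from")
        X = np.asarray(X, dtype=float)
        flat = X[:, 0] if X.ndim == 2 else X
        return evaluate_model(self.result_.spec, flat)
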