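"""Bootstrap confidence intervals and CI-based difference detection.

Single curves
-------------
Nonparametric bootstrap: (time, value) pairs are resampled with
replacement, the chosen estimator (spline or growth model) is refitted,
and percentile intervals are formed from the resampled parameter draws
(default level 0.95, B = 100).  Two curves differ detectably in a
parameter when their intervals do not overlap; the gap between the nearer
opposite limits is then the *minimum expectable difference* -- a lower
bound on the underlying effect, directly on the measurement scale.  This
per-curve workflow deliberately applies no multiplicity adjustment: the
aim of an exploratory PM screen is to surface every candidate difference.

Groups of curves
----------------
Two complementary devices:

* :func:`group_mean_cis` averages member points and member CI limits --
  a quick visualization device, *not* a valid testing procedure (so
  documented, so flagged).
* :func:`simultaneous_mean_differences` is the proper procedure: a one-way
  layout on the per-curve point estimates, user-defined contrasts of group
  means, and simultaneous intervals from the max-|t| critical value of the
  contrast set (seeded Monte Carlo on the multivariate t implied by the
  contrast correlation structure; Bonferroni fallback).  An interval that
  excludes zero flags a statistically detectable difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .core import PARAMETER_NAMES, KineticCurve, ParameterCI
from .spline import fit_spline, spline_parameters

__all__ = [
    "bootstrap_cis",
    "OverlapResult",
    "ci_overlap_minimum_difference",
    "group_mean_cis",
    "GroupComparison",
    "simultaneous_mean_differences",
    "all_pairs_contrasts",
    "vs_control_contrasts",
]

_DEFAULT_B = 100
_MAX_FAILED_FRACTION = 0.5


def _fit_point_estimates(
    times: np.ndarray,
    values: np.ndarray,
    method: str,
    model_name: str,
    smoothing,
    span: Optional[Tuple[float, float]] = None,
) -> Optional[Dict[str, float]]:
    """One (re)fit; returns the four parameters or None on failure.

    ``span`` fixes the evaluation window for A/mu/AUC extraction so that
    bootstrap resamples missing the first or last reading are still
    measured over the original time range.
    """
    from .core import WellCoordinate
    from .growth_models import MODEL_NAMES, evaluate_model, fit_model_arrays

    if method == "spline":
        try:
            curve = KineticCurve(times=times, values=values, well=WellCoordinate("A", 1))
            params = spline_parameters(fit_spline(curve, smoothing=smoothing), span=span)
        except Exception:
            return None
        return params.as_dict()
    if method == "model":
        if model_name == "auto":
            fits = [fit_model_arrays(times, values, name) for name in MODEL_NAMES]
            converged = [f for f in fits if f.converged]
            if not converged:
                return None
            order = {name: i for i, name in enumerate(MODEL_NAMES)}
            best = min(converged, key=lambda r: (r.aic, r.n_params, order[r.name]))
        else:
            best = fit_model_arrays(times, values, model_name)
            if not best.converged:
                return None
        out = best.parameters.as_dict()
        if span is not None:
            dense = np.linspace(span[0], span[1], 4 * times.size)
            out["AUC"] = float(np.trapezoid(evaluate_model(best.spec, dense), dense))
        return out
    raise ValueError(f"unknown method {method!r} (use 'spline' or 'model')")


def _collapse_duplicate_times(t: np.ndarray, v: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Average values sharing a time point; splines need strictly increasing x."""
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    uniq, inverse, counts = np.unique(t, return_inverse=True, return_counts=True)
    sums = np.zeros_like(uniq)
    np.add.at(sums, inverse, v)
    return uniq, sums / counts


def bootstrap_cis(
    curve: KineticCurve,
    method: str = "spline",
    B: int = _DEFAULT_B,
    level: float = 0.95,
    seed: Optional[int] = None,
    model_name: str = "auto",
    smoothing: Union[str, float, None] = "auto",
) -> Dict[str, ParameterCI]:
    """Percentile bootstrap CIs for all four parameters of one curve.

    Observation pairs are resampled with replacement; for the spline
    method, resampled duplicates at the same time are averaged (as tied x
    values are in classical smoothing-spline fitting).  Replicates whose
    refit fails (or yields non-finite parameters) are dropped and counted;
    if more than half fail, the intervals are flagged ``unreliable``.
    With a fixed seed the intervals are reproducible.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    clean = curve.dropna()
    t, v = clean.times, clean.values
    point = _fit_point_estimates(t, v, method, model_name, smoothing)
    if point is None:
        raise ValueError(f"curve {curve.well.label} is not fittable by method {method!r}")

    rng = np.random.default_rng(seed)
    n = t.size
    span = (float(t[0]), float(t[-1]))
    draws = {name: [] for name in PARAMETER_NAMES}
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        tb, vb = t[idx], v[idx]
        if method == "spline":
            # tied abscissae are averaged, as in classical smoothing-spline fitting
            tb, vb = _collapse_duplicate_times(tb, vb)
        est = (
            _fit_point_estimates(tb, vb, method, model_name, smoothing, span=span)
            if tb.size >= 4
            else None
        )
        if est is None or not all(
            math.isfinite(est[k]) for k in ("mu", "A", "AUC")
        ):
            n_failed += 1
            continue
        for name in PARAMETER_NAMES:
            draws[name].append(est[name])

    unreliable = n_failed > _MAX_FAILED_FRACTION * B
    alpha = (1.0 - level) / 2.0
    out: Dict[str, ParameterCI] = {}
    for name in PARAMETER_NAMES:
        arr = np.asarray(draws[name], dtype=float)
        arr = arr[np.isfinite(arr)]
        flags: List[str] = []
        if unreliable:
            flags.append("unreliable")
        if arr.size < 2:
            lo = hi = math.nan
            flags.append("no_successful_refits")
        else:
            lo = float(np.quantile(arr, alpha))
            hi = float(np.quantile(arr, 1.0 - alpha))
        pt = point[name]
        if math.isfinite(lo) and math.isfinite(pt) and not (lo <= pt <= hi):
            flags.append("point_outside_interval")
        out[name] = ParameterCI(
            parameter=name,
            point=pt,
            lower=lo,
            upper=hi,
            level=level,
            n_boot=B,
            n_failed=n_failed,
            flags=tuple(flags),
        )
    return out


@dataclass(frozen=True)
class OverlapResult:
    """CI-overlap decision between two intervals of the same parameter."""

    overlaps: bool
    #: Signed gap between the nearer opposite limits when disjoint
    #: (positive when ``b`` lies above ``a``); 0 when the intervals touch
    #: or overlap.  A lower bound on the underlying mean difference.
    min_expected_difference: float


def ci_overlap_minimum_difference(a: ParameterCI, b: ParameterCI) -> OverlapResult:
    """Detect a difference between two curves via CI overlap.

    Intervals are treated as closed: a shared endpoint counts as overlap
    (the conservative convention).
    """
    if a.parameter != b.parameter:
        raise ValueError(f"parameter mismatch: {a.parameter} vs {b.parameter}")
    if a.level != b.level:
        raise ValueError(f"level mismatch: {a.level} vs {b.level}")
    if b.lower > a.upper:
        return OverlapResult(False, float(b.lower - a.upper))
    if a.lower > b.upper:
        return OverlapResult(False, -float(a.lower - b.upper))
    return OverlapResult(True, 0.0)


def group_mean_cis(
    groups: Mapping[str, Sequence[ParameterCI]]
) -> Dict[str, ParameterCI]:
    """Average member points and member CI limits per group.

    A quick, impartial visualization device for group behavior.  The
    averaged limits are *not* a confidence interval for the group mean and
    must not be used as a test; use
    :func:`simultaneous_mean_differences` for decisions.
    """
    out: Dict[str, ParameterCI] = {}
    for name, members in groups.items():
        members = list(members)
        if not members:
            raise ValueError(f"group {name!r} is empty")
        params = {m.parameter for m in members}
        levels = {m.level for m in members}
        if len(params) > 1 or len(levels) > 1:
            raise ValueError(f"group {name!r} mixes parameters or levels")
        out[name] = ParameterCI(
            parameter=members[0].parameter,
            point=float(np.mean([m.point for m in members])),
            lower=float(np.mean([m.lower for m in members])),
            upper=float(np.mean([m.upper for m in members])),
            level=members[0].level,
            flags=("mean_of_cis",),
        )
    return out


def all_pairs_contrasts(n_groups: int) -> np.ndarray:
    """Tukey-type all-pairwise contrast matrix (each row sums to 0)."""
    rows = []
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            row = np.zeros(n_groups)
            row[j] = 1.0
            row[i] = -1.0
            rows.append(row)
    return np.array(rows)


def vs_control_contrasts(n_groups: int, control: int = 0) -> np.ndarray:
    """Dunnett-type many-to-one contrasts against a control group."""
    rows = []
    for j in range(n_groups):
        if j == control:
            continue
        row = np.zeros(n_groups)
        row[j] = 1.0
        row[control] = -1.0
        rows.append(row)
    return np.array(rows)


@dataclass
class GroupComparison:
    """Simultaneous CIs for user-defined differences of group means."""

    groups: Tuple[str, ...]
    contrasts: np.ndarray        # m x g, rows sum to 0
    estimates: np.ndarray        # contrast point estimates
    std_errors: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    df: int
    critical_value: float
    method: str                  # "mc-max-t" or "bonferroni"

    @property
    def significant(self) -> np.ndarray:
        """True where the interval excludes zero (detectable difference)."""
        return (self.lower > 0) | (self.upper < 0)


def _max_t_critical(
    R: np.ndarray, df: int, level: float, rng: np.random.Generator, n_draws: int
) -> float:
    """Equicoordinate critical value of max |t| over correlated contrasts."""
    m = R.shape[0]
    z = rng.multivariate_normal(np.zeros(m), R, size=n_draws, method="eigh")
    chi = rng.chisquare(df, size=n_draws) / df
    tmax = np.max(np.abs(z), axis=1) / np.sqrt(chi)
    return float(np.quantile(tmax, level))


def simultaneous_mean_differences(
    groups: Mapping[str, Sequence[float]],
    contrasts: Union[np.ndarray, str] = "all-pairs",
    level: float = 0.95,
    seed: Optional[int] = None,
    n_draws: int = 100_000,
) -> GroupComparison:
    """Simultaneous 95% CIs for differences of group parameter means.

    ``groups`` maps group labels to the per-curve point estimates of one
    parameter.  A one-way homoscedastic model provides the pooled variance;
    the simultaneous quantile is the ``level`` quantile of max-|t| over the
    contrast set, obtained by seeded Monte Carlo from the multivariate t
    distribution implied by the contrasts' correlation matrix.  For a
    single contrast this reduces to the classical pooled two-sample t
    interval (up to Monte-Carlo error in the quantile).
    """
    labels = tuple(groups.keys())
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    sizes = np.array([d.size for d in data])
    if np.any(sizes < 1):
        raise ValueError("every group needs at least one member")
    N = int(sizes.sum())
    df = N - g
    if df < 1:
        raise ValueError("no residual degrees of freedom for variance estimation")

    if isinstance(contrasts, str):
        if contrasts == "all-pairs":
            C = all_pairs_contrasts(g)
        elif contrasts == "vs-control":
            C = vs_control_contrasts(g)
        else:
            raise ValueError(f"unknown contrast set {contrasts!r}")
    else:
        C = np.asarray(contrasts, dtype=float)
    if C.ndim != 2 or C.shape[1] != g:
        raise ValueError(f"contrast matrix must have {g} columns")
    bad = np.nonzero(np.abs(C.sum(axis=1)) > 1e-10)[0]
    if bad.size:
        raise ValueError(f"contrast row {int(bad[0])} does not sum to zero: {C[bad[0]]}")

    means = np.array([d.mean() for d in data])
    sse = float(sum(((d - d.mean()) ** 2).sum() for d in data))
    s2 = sse / df
    est = C @ means
    var_scale = (C**2 / sizes).sum(axis=1)  # c' diag(1/n) c
    se = np.sqrt(s2 * var_scale)

    cov = (C / sizes) @ C.T
    d = np.sqrt(np.diag(cov))
    if np.any(d <= 0) or not np.all(np.isfinite(cov)):
        raise ValueError("singular contrast structure (zero-variance contrast row)")
    R = cov / np.outer(d, d)

    rng = np.random.default_rng(seed)
    method = "mc-max-t"
    try:
        crit = _max_t_critical(R, df, level, rng, n_draws)
    except np.linalg.LinAlgError:
        m = C.shape[0]
        crit = float(stats.t.ppf(1.0 - (1.0 - level) / (2.0 * m), df))
        method = "bonferroni"

    return GroupComparison(
        groups=labels,
        contrasts=C,
        estimates=est,
        std_errors=se,
        lower=est - crit * se,
        upper=est + crit * se,
        level=level,
        df=df,
        critical_value=crit,
        method=method,
    )
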