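"""Post-processing of curve-parameter tables.

Positive/negative calls, lag-distribution truncation, archetypal analysis
of curve shapes (how many characteristic shape classes does a dataset
contain?) and rank correlations between parameters and between fitting
methods.

Archetypal analysis represents each observation (a curve's (lambda, mu, A,
AUC) vector) as a convex combination of k *archetypes*, themselves convex
combinations of observations: minimize ||X - C Z||^2 with C rows on the
simplex and Z = B X, B rows on the simplex.  The alternating algorithm
solves convex least-squares subproblems for C given Z and for B given C,
so the residual sum of squares is non-increasing.  Restarting over
k = 1..10 and applying the elbow criterion to the RSS scree chooses the
number of shape classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import kendalltau, spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .core import CurveParameters

__all__ = [
    "call_reaction",
    "POSITIVITY_THRESHOLD",
    "truncate_lambda",
    "ArchetypalAnalysis",
    "ArchetypeModel",
    "fit_archetypes",
    "StepArchetypesResult",
    "step_archetypes_elbow",
    "parameter_correlations",
]

#: Maximum-height threshold (OmniLog units) separating positive from
#: negative reactions.  Partially arbitrary by construction; a rough
#: dichotomization device, refined by the archetype analysis.
POSITIVITY_THRESHOLD = 100.0

_SIMPLEX_PENALTY = 200.0  # weight of the sum-to-one row in the NNLS systems


def call_reaction(
    params: Union[CurveParameters, float], threshold: float = POSITIVITY_THRESHOLD
) -> Optional[str]:
    """Dichotomize a curve into ``"positive"``/``"negative"`` by its A.

    Strictly greater than the threshold is positive; missing A yields no
    call (``None``).
    """
    A = params.A if isinstance(params, CurveParameters) else float(params)
    if A is None or (isinstance(A, float) and math.isnan(A)):
        return None
    return "positive" if A > threshold else "negative"


def truncate_lambda(values) -> np.ndarray:
    """Symmetrize a lag-phase column by clamping extreme negative outliers.

    With ``M = max(values)``, every value below ``-M`` is set to ``-M``;
    everything else (including NaN) is untouched.  Near-flat drifting
    wells can produce lag estimates hundreds of hours before the start of
    the measurement; truncation keeps them from dominating the archetype
    geometry while preserving their sign.  Idempotent.
    """
    arr = np.asarray(values, dtype=float).copy()
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("lambda column has no finite values")
    M = float(np.max(finite))
    with np.errstate(invalid="ignore"):
        arr[arr < -M] = -M
    return arr


# ---------------------------------------------------------------------------
# archetypal analysis


def _simplex_nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||A x - b|| s.t. x >= 0, sum(x) = 1, via a penalty row."""
    m = A.shape[1]
    A_aug = np.vstack([A, _SIMPLEX_PENALTY * np.ones((1, m))])
    b_aug = np.concatenate([b, [_SIMPLEX_PENALTY]])
    x, _ = nnls(A_aug, b_aug)
    s = x.sum()
    if s > 0:
        x = x / s
    return x


def _coefficients_for(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Best simplex coefficients row-wise: min ||X - C Z||."""
    At = Z.T  # d x k
    return np.array([_simplex_nnls(At, x) for x in X])


def _archetypes_for(X: np.ndarray, C: np.ndarray, k: int) -> np.ndarray:
    """Best archetype weights B (k x n, rows on the simplex): Z = B X."""
    # unconstrained optimum of Z given C, then project each archetype back
    # onto the convex hull of the data
    Z_tilde, *_ = np.linalg.lstsq(C, X, rcond=None)
    B = np.array([_simplex_nnls(X.T, z) for z in Z_tilde])
    return B


@dataclass
class ArchetypeModel:
    """A fitted set of curve-shape archetypes."""

    k: int
    archetypes: np.ndarray       # k x d, original parameter units
    coefficients: np.ndarray     # n x k, rows on the simplex
    weights: np.ndarray          # k x n, rows on the simplex (archetype = weights @ X)
    rss: float                   # on the fitting (standardized) scale
    rss_path: np.ndarray         # accepted-iteration RSS trace, non-increasing
    restarts: int
    seed: Optional[int]
    converged: bool
    columns: Optional[Tuple[str, ...]] = None


class ArchetypalAnalysis(BaseEstimator, TransformerMixin):
    """Archetypal analysis of curve-parameter vectors (sklearn-style).

    Parameters
    ----------
    n_archetypes : int
        Number of archetypes k (1 <= k <= n samples).
    max_iter, tol : alternating-minimization controls; iteration stops at
        relative RSS improvement below ``tol`` (or any RSS increase, so
        the recorded trace is non-increasing).
    n_restarts : best-of random restarts.
    standardize : bool, default=True
        Fit on zero-mean/unit-variance columns (the four parameters live
        on wildly different scales); archetypes are reported back in
        original units.
    random_state : seed for the random simplex initialization.

    Attributes
    ----------
    archetypes_ : (k, d) archetypes in original units.
    coefficients_ : (n, k) simplex rows reconstructing the training data.
    rss_ : residual sum of squares on the fitting scale.
    rss_path_ : accepted RSS trace of the best restart.
    converged_ : bool
    """

    def __init__(
        self,
        n_archetypes: int = 3,
        max_iter: int = 200,
        tol: float = 1e-6,
        n_restarts: int = 1,
        standardize: bool = True,
        random_state: Optional[int] = None,
    ):
        self.n_archetypes = n_archetypes
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.standardize = standardize
        self.random_state = random_state

    def _run_once(self, Xs: np.ndarray, rng: np.random.Generator):
        n, d = Xs.shape
        k = self.n_archetypes
        C = rng.dirichlet(np.ones(k), size=n)
        B = _archetypes_for(Xs, C, k)
        Z = B @ Xs
        C = _coefficients_for(Xs, Z)
        rss = float(((Xs - C @ Z) ** 2).sum())
        path = [rss]
        converged = False
        for _ in range(self.max_iter):
            B_new = _archetypes_for(Xs, C, k)
            Z_new = B_new @ Xs
            C_new = _coefficients_for(Xs, Z_new)
            rss_new = float(((Xs - C_new @ Z_new) ** 2).sum())
            if rss_new > rss:
                # the penalty-row approximation can produce a marginal
                # uphill step; stop and keep the previous iterate
                converged = True
                break
            improvement = rss - rss_new
            B, Z, C, rss = B_new, Z_new, C_new, rss_new
            path.append(rss)
            if improvement <= self.tol * max(rss, 1e-12):
                converged = True
                break
        return C, Z, B, rss, np.asarray(path), converged

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n, d = X.shape
        k = self.n_archetypes
        if not 1 <= k <= n:
            raise ValueError(f"need 1 <= n_archetypes <= n_samples, got k={k}, n={n}")
        if np.any(~np.isfinite(X)):
            raise ValueError("X contains non-finite entries; drop unfittable rows first")

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0)
            scale[scale == 0] = 1.0
            self.scale_ = scale
        else:
            self.mean_ = np.zeros(d)
            self.scale_ = np.ones(d)
        Xs = (X - self.mean_) / self.scale_

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            out = self._run_once(Xs, rng)
            if best is None or out[3] < best[3]:
                best = out
        C, Z, B, rss, path, converged = best
        self.coefficients_ = C
        self.weights_ = B
        self.archetypes_std_ = Z
        self.archetypes_ = Z * self.scale_ + self.mean_
        self.rss_ = rss
        self.rss_path_ = path
        self.converged_ = converged
        return self

    def transform(self, X):
        """Simplex coefficients of new observations on the fitted archetypes."""
        check_is_fitted(self, "archetypes_std_")
        X = np.asarray(X, dtype=float)
        Xs = (X - self.mean_) / self.scale_
        return _coefficients_for(Xs, self.archetypes_std_)


def fit_archetypes(
    X,
    k: int,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: Optional[int] = None,
    n_restarts: int = 1,
    standardize: bool = True,
    columns: Optional[Sequence[str]] = None,
) -> ArchetypeModel:
    """Functional wrapper around :class:`ArchetypalAnalysis`."""
    if isinstance(X, pd.DataFrame):
        columns = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    est = ArchetypalAnalysis(
        n_archetypes=k,
        max_iter=max_iter,
        tol=tol,
        n_restarts=n_restarts,
        standardize=standardize,
        random_state=seed,
    ).fit(X)
    return ArchetypeModel(
        k=k,
        archetypes=est.archetypes_,
        coefficients=est.coefficients_,
        weights=est.weights_,
        rss=est.rss_,
        rss_path=est.rss_path_,
        restarts=n_restarts,
        seed=seed,
        converged=est.converged_,
        columns=tuple(columns) if columns else None,
    )


@dataclass
class StepArchetypesResult:
    """RSS scree over k plus the elbow-selected number of archetypes."""

    k_values: Tuple[int, ...]
    rss: Dict[int, float]          # best-of-restarts RSS per k
    models: Dict[int, ArchetypeModel]
    selected_k: int
    drops: Dict[int, float]        # RSS(k-1) - RSS(k)

    def scree(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": list(self.k_values), "rss": [self.rss[k] for k in self.k_values]}
        )


def _elbow_select(k_values: Sequence[int], rss: Dict[int, float]) -> Tuple[int, Dict[int, float]]:
    """The k whose RSS drop is largest *relative to subsequent improvements*.

    For each k (except the last, which has no subsequent drops to compare
    against) the drop ``RSS(k-1) - RSS(k)`` is scored against the largest
    later drop; the k with the highest ratio wins, ties going to the
    smaller k.  On data with planted vertex structure this lands on the
    last big step before the scree flattens; on structureless data the
    drops decay smoothly and the first dominating drop wins.
    """
    ks = sorted(k_values)
    drops = {k: rss[prev] - rss[k] for prev, k in zip(ks, ks[1:])}
    if not drops:
        return ks[0], {}
    drop_ks = sorted(drops)
    # drops below ~1e-6 of the overall scale are numerical noise: clamping
    # the comparison there keeps flat scree tails from producing huge ratios
    floor = 1e-6 * max(abs(rss[ks[0]]), 1.0)
    scored = []
    for i, k in enumerate(drop_ks[:-1]):
        later = max(drops[j] for j in drop_ks[i + 1:])
        scored.append((max(drops[k], 0.0) / max(later, floor), -k))
    if scored:
        best = -max(scored)[1]
    else:  # only one drop observable
        best = drop_ks[0]
    return best, drops


def step_archetypes_elbow(
    X,
    k_range: Iterable[int] = range(1, 11),
    restarts: int = 5,
    seed: Optional[int] = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    standardize: bool = True,
) -> StepArchetypesResult:
    """Fit archetypes over a range of k and elbow-select the optimal count.

    Per k the best of ``restarts`` random starts is kept.  The optimal k
    is the one whose RSS drop from k-1 is the largest among the drops that
    exceed all subsequent drops -- the "largest step towards a lower RSS
    compared to subsequent improvements".
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    if ks[0] < 1 or ks[-1] > X.shape[0]:
        raise ValueError(f"k_range must lie within [1, {X.shape[0]}]")

    seed_seq = np.random.SeedSequence(seed)
    models: Dict[int, ArchetypeModel] = {}
    rss: Dict[int, float] = {}
    for k, child in zip(ks, seed_seq.spawn(len(ks))):
        model = fit_archetypes(
            X,
            k,
            max_iter=max_iter,
            tol=tol,
            seed=int(child.generate_state(1)[0] % (2**31)),
            n_restarts=restarts,
            standardize=standardize,
        )
        models[k] = model
        rss[k] = model.rss
    best_rss = [rss[k] for k in ks]
    # increases below ~0.01% of the overall RSS scale are restart jitter
    jitter = 1e-4 * max(abs(best_rss[0]), 1.0)
    if any(b > a + jitter for a, b in zip(best_rss, best_rss[1:])):
        warnings.warn(
            "best-of-restarts RSS is not monotone in k (restart failure); "
            "elbow selection proceeds on the observed drops",
            RuntimeWarning,
        )
    selected, drops = _elbow_select(ks, rss)
    return StepArchetypesResult(
        k_values=tuple(ks), rss=rss, models=models, selected_k=selected, drops=drops
    )


# ---------------------------------------------------------------------------
# correlations


def parameter_correlations(
    table: pd.DataFrame, method: str = "spearman"
) -> pd.DataFrame:
    """All-against-all rank correlations of parameter columns.

    Rows with any missing entry are dropped (pairwise-complete would mix
    sample bases across cells).  Constant columns yield NaN.  ``method``
    is ``"spearman"`` or ``"kendall"``.
    """
    if method not in {"spearman", "kendall"}:
        raise ValueError(f"method must be 'spearman' or 'kendall', got {method!r}")
    complete = table.dropna()
    if len(complete) < 3:
        raise ValueError("need >= 3 complete rows for rank correlations")
    cols = list(table.columns)
    k = len(cols)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x = complete[cols[i]].to_numpy(dtype=float)
            y = complete[cols[j]].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # correlation undefined for a constant column
            if method == "spearman":
                r = spearmanr(x, y).statistic
            else:
                r = kendalltau(x, y).statistic
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=cols, columns=cols)
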