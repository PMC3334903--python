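"""Batch parameter estimation over plates and reliability accounting.

Runs one of the three estimation methods over every curve of a set of
plates and summarizes reliability the way PM method comparisons are
reported: how many curves had no fittable model / spline, how many
estimates were biologically implausible (negative lag, A above the 400
unit instrument cap), and how many fall below the 100-unit positivity
threshold.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .core import OMNILOG_CAP, CurveParameters, KineticCurve, Plate
from .growth_models import select_best_model, fit_model
from .native import native_parameters
from .plate_io import ParameterRecord
from .shapes import POSITIVITY_THRESHOLD, call_reaction
from .spline import fit_spline, spline_parameters

__all__ = ["estimate_parameters", "parameters_frame", "reliability_summary"]


def _fit_one(curve: KineticCurve, method: str, model_name: str, smoothing) -> CurveParameters:
    if method == "native":
        params, _ = native_parameters(curve)
        return params
    if method == "model":
        if model_name == "auto":
            best, _ = select_best_model(curve)
        else:
            best = fit_model(curve, model_name)
        if not best.converged:
            return CurveParameters(
                math.nan, math.nan, math.nan, math.nan,
                method="model", model_name=None, fit_ok=False,
                flags=("unfittable",),
            )
        return best.parameters
    if method == "spline":
        try:
            return spline_parameters(fit_spline(curve, smoothing=smoothing))
        except ValueError:
            return CurveParameters(
                math.nan, math.nan, math.nan, math.nan,
                method="spline", fit_ok=False, flags=("unfittable",),
            )
    raise ValueError(f"unknown method {method!r}")


def estimate_parameters(
    plates: Union[Plate, Sequence[Plate]],
    method: str = "spline",
    model_name: str = "auto",
    smoothing: Union[str, float, None] = "auto",
) -> List[ParameterRecord]:
    """Fit every curve of the given plates with one method."""
    if isinstance(plates, Plate):
        plates = [plates]
    records: List[ParameterRecord] = []
    for plate in plates:
        for curve in plate:
            params = _fit_one(curve, method, model_name, smoothing)
            records.append(
                ParameterRecord(
                    params=params,
                    well=curve.well,
                    dataset_id=plate.dataset_id,
                    plate_id=plate.plate_id,
                    substrate=curve.substrate,
                )
            )
    return records


def parameters_frame(records: Sequence[ParameterRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame (one row per curve and method)."""
    rows = []
    for rec in records:
        p = rec.params
        rows.append(
            {
                "dataset_id": rec.dataset_id,
                "plate_id": rec.plate_id,
                "well": rec.well.label,
                "method": p.method,
                "model_name": p.model_name,
                "fit_ok": p.fit_ok,
                "lambda": p.lambda_,
                "mu": p.mu,
                "A": p.A,
                "AUC": p.auc,
                "flags": ";".join(p.flags),
                "call": call_reaction(p) if p.fit_ok else None,
            }
        )
    return pd.DataFrame(rows)


def reliability_summary(
    df: pd.DataFrame, group_columns: Optional[Sequence[str]] = None
) -> Dict[str, float]:
    """Reliability accounting for one method's parameter frame.

    Counts unfittable curves and implausible estimates (lambda < 0,
    A > 400) plus the A < 100 proportion (approximate negative reactions).
    ``group_columns`` optionally adds group-level accounting: a group is
    "without fittable estimates" when none of its member curves is.
    """
    n = len(df)
    unfittable = int((~df["fit_ok"]).sum())
    fitted = df[df["fit_ok"]]
    out: Dict[str, float] = {
        "n_curves": n,
        "n_unfittable": unfittable,
        "pct_unfittable": 100.0 * unfittable / n if n else math.nan,
        "n_lambda_negative": int((fitted["lambda"] < 0).sum()),
        "n_A_above_cap": int((fitted["A"] > OMNILOG_CAP).sum()),
        "n_A_below_100": int((fitted["A"] < POSITIVITY_THRESHOLD).sum()),
    }
    if group_columns:
        grouped = df.groupby(list(group_columns), dropna=False)
        out["n_groups"] = int(grouped.ngroups)
        out["n_groups_unfittable"] = int((~grouped["fit_ok"].any()).sum())
    return out
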