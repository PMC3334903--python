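"""Read/write OmniLog-dialect plate CSVs and flag raw-data artifacts.

Dialect
-------
A file holds one or more plate blocks.  Each block is::

    # plate_id=PM01-1
    # dataset_id=run-2026-01
    # strain=E. coli K12
    Hour,A01,A02,...,H12
    0.0,12.0,9.5,...,11.0
    0.25,12.5,10.1,...,11.2
    ...

Leading ``#`` lines carry ``key=value`` metadata applied to the whole
block; the header has one time column (``Hour`` or ``Time``, decimal
hours) followed by well columns.  Well labels are accepted zero-padded or
not ("A01"/"A1") and always emitted zero-padded.

Negative-control subtraction (well A01 from all others) is available via
:func:`subtract_negative_control` but deliberately not applied anywhere by
default: control wells can show reproducible, strain-specific growth-like
signals larger than genuine negative reactions, so treating them as an
additive error term distorts curve shapes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .core import (
    PARAMETER_NAMES,
    CurveParameters,
    KineticCurve,
    ParameterCI,
    Plate,
    WellCoordinate,
)

__all__ = [
    "ParseError",
    "ArtifactReport",
    "ParameterRecord",
    "PARAMETER_TABLE_COLUMNS",
    "read_omnilog_csv",
    "write_omnilog_csv",
    "write_parameter_table",
    "read_parameter_table",
    "flag_curve_artifacts",
    "subtract_negative_control",
]

TIME_COLUMN_NAMES = {"hour", "hours", "time", "time_h"}

#: Fixed column layout of the shared parameter table.
PARAMETER_TABLE_COLUMNS = [
    "dataset_id",
    "plate_id",
    "well",
    "substrate",
    "method",
    "model_name",
    "lambda",
    "lambda_lo",
    "lambda_hi",
    "mu",
    "mu_lo",
    "mu_hi",
    "A",
    "A_lo",
    "A_hi",
    "AUC",
    "AUC_lo",
    "AUC_hi",
]


class ParseError(ValueError):
    """Raised when a plate CSV violates the dialect."""


@dataclass(frozen=True)
class ArtifactReport:
    """A raw-data irregularity in one curve.

    ``kind`` is ``"non-monotone-drop"`` (a maximal run of consecutive
    readings whose total decrease exceeds the tolerance) or
    ``"transient-spike"`` (a single reading above both neighbors by more
    than the tolerance).  ``indices`` are the affected sample indices and
    ``magnitude`` the total drop / the excursion above the higher neighbor.
    """

    well: WellCoordinate
    kind: str
    indices: tuple
    magnitude: float


# ---------------------------------------------------------------------------
# plate CSV


def _open_text(source, mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, newline=""), True


def _split_blocks(lines: Sequence[str]) -> List[tuple]:
    """Group lines into (metadata-lines, csv-lines) blocks.

    A new block starts at each run of ``#`` lines that follows data, or at
    a repeated header line.
    """
    blocks: List[tuple] = []
    meta: List[str] = []
    body: List[str] = []
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.lstrip().startswith("#"):
            if body:
                blocks.append((meta, body))
                meta, body = [], []
            meta.append(line.lstrip().lstrip("#").strip())
        else:
            first = line.split(",", 1)[0].strip().lower()
            if body and first in TIME_COLUMN_NAMES:
                blocks.append((meta, body))
                meta, body = [], []
            body.append(line)
    if meta or body:
        blocks.append((meta, body))
    return blocks


def _parse_metadata(meta_lines: Iterable[str]) -> dict:
    meta = {}
    for line in meta_lines:
        if "=" in line:
            key, _, value = line.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _parse_block(meta_lines: Sequence[str], body: Sequence[str]) -> Plate:
    if not body:
        raise ParseError("empty plate block")
    meta = _parse_metadata(meta_lines)
    df = pd.read_csv(_io.StringIO("\n".join(body)), float_precision="round_trip")
    header = list(df.columns)
    if not header or str(header[0]).strip().lower() not in TIME_COLUMN_NAMES:
        raise ParseError(
            f"first column must be a time column (one of {sorted(TIME_COLUMN_NAMES)}), "
            f"got {header[0]!r}" if header else "missing header"
        )
    wells = []
    for col in header[1:]:
        try:
            wells.append(WellCoordinate.from_label(str(col)))
        except ValueError as exc:
            raise ParseError(f"malformed well column {col!r}") from exc
    if not wells:
        raise ParseError("header contains no well columns")
    times = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise ParseError("time column contains non-finite entries")
    if np.any(np.diff(times) <= 0):
        raise ParseError("time column is not strictly increasing")
    cultivation = meta.get("cultivation_hours")
    curves = {}
    for coord, col in zip(wells, header[1:]):
        values = df[col].to_numpy(dtype=float)
        curves[coord.label] = KineticCurve(
            times=times,
            values=values,
            well=coord,
            strain=meta.get("strain"),
            biological_replicate=meta.get("biological_replicate"),
            technical_replicate=meta.get("technical_replicate"),
            cultivation_hours=float(cultivation) if cultivation is not None else None,
            substrate=None,
        )
    return Plate(curves, plate_id=meta.get("plate_id"), dataset_id=meta.get("dataset_id"))


def read_omnilog_csv(source: Union[str, Path, TextIO]) -> List[Plate]:
    """Read one or more plates from an OmniLog-dialect CSV.

    Returns the plates in file order.  Missing wells are simply absent from
    ``plate.curves`` and listed by ``plate.missing_wells``.
    """
    handle, should_close = _open_text(source, "r")
    try:
        lines = handle.read().splitlines()
    finally:
        if should_close:
            handle.close()
    blocks = _split_blocks(lines)
    if not blocks:
        raise ParseError("no plate blocks found")
    return [_parse_block(meta, body) for meta, body in blocks]


def write_omnilog_csv(plates: Union[Plate, Sequence[Plate]], sink) -> None:
    """Write plates in the dialect read by :func:`read_omnilog_csv`.

    Floats are written with ``repr`` so that a read/write round trip is
    bit-exact.
    """
    if isinstance(plates, Plate):
        plates = [plates]
    handle, should_close = _open_text(sink, "w")
    try:
        for plate in plates:
            labels = sorted(plate.curves)
            first = plate.curves[labels[0]]
            meta = {
                "plate_id": plate.plate_id,
                "dataset_id": plate.dataset_id,
                "strain": first.strain,
                "biological_replicate": first.biological_replicate,
                "technical_replicate": first.technical_replicate,
                "cultivation_hours": first.cultivation_hours,
            }
            for key, value in meta.items():
                if value is not None:
                    handle.write(f"# {key}={value}\n")
            handle.write("Hour," + ",".join(labels) + "\n")
            times = plate.times
            columns = [plate.curves[lab].values for lab in labels]
            for i, t in enumerate(times):
                row = [repr(float(t))] + [
                    "" if np.isnan(col[i]) else repr(float(col[i])) for col in columns
                ]
                handle.write(",".join(row) + "\n")
    finally:
        if should_close:
            handle.close()


# ---------------------------------------------------------------------------
# parameter table


@dataclass
class ParameterRecord:
    """One (curve, method) row of the shared parameter table."""

    params: CurveParameters
    well: WellCoordinate
    dataset_id: Optional[str] = None
    plate_id: Optional[str] = None
    substrate: Optional[str] = None
    cis: Optional[Mapping[str, ParameterCI]] = None


def write_parameter_table(records: Sequence[ParameterRecord], sink) -> None:
    """Write the fixed 18-column parameter table, deterministically ordered.

    All confidence intervals across all rows must share one level (or be
    absent); CI cells are empty when not computed.
    """
    levels = {
        ci.level
        for rec in records
        if rec.cis
        for ci in rec.cis.values()
    }
    if len(levels) > 1:
        raise ValueError(f"mixed CI levels in one table: {sorted(levels)}")
    rows = []
    for rec in records:
        p = rec.params.as_dict()
        row = {
            "dataset_id": rec.dataset_id,
            "plate_id": rec.plate_id,
            "well": rec.well.label,
            "substrate": rec.substrate,
            "method": rec.params.method,
            "model_name": rec.params.model_name,
        }
        for name in PARAMETER_NAMES:
            row[name] = p[name]
            ci = rec.cis.get(name) if rec.cis else None
            row[f"{name}_lo"] = ci.lower if ci else np.nan
            row[f"{name}_hi"] = ci.upper if ci else np.nan
        rows.append(row)
    df = pd.DataFrame(rows, columns=PARAMETER_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["dataset_id", "plate_id", "well", "method"], na_position="first"
        ).reset_index(drop=True)
    handle, should_close = _open_text(sink, "w")
    try:
        df.to_csv(handle, index=False, lineterminator="\n")
    finally:
        if should_close:
            handle.close()


def read_parameter_table(source) -> pd.DataFrame:
    """Read a parameter table back into a DataFrame with the fixed layout."""
    handle, should_close = _open_text(source, "r")
    try:
        df = pd.read_csv(handle, float_precision="round_trip")
    finally:
        if should_close:
            handle.close()
    missing = [c for c in PARAMETER_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"parameter table lacks columns: {missing}")
    return df[PARAMETER_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# raw-data artifacts


def flag_curve_artifacts(curve: KineticCurve, drop_tol: float) -> List[ArtifactReport]:
    """Report non-monotone drops and transient spikes in a raw curve.

    Respiration signals should increase monotonically (the dye reduction is
    irreversible); decreasing stretches and single-sample peaks point at
    technical problems.  A *drop* is a maximal run of consecutive
    non-increasing steps whose total decrease exceeds ``drop_tol``; a
    *spike* is a single reading exceeding both neighbors by more than
    ``drop_tol``.
    """
    if drop_tol <= 0:
        raise ValueError("drop_tol must be positive")
    v = curve.values
    n = v.size
    reports: List[ArtifactReport] = []

    # maximal non-increasing runs
    i = 0
    while i < n - 1:
        if v[i + 1] <= v[i]:
            j = i
            while j < n - 1 and v[j + 1] <= v[j]:
                j += 1
            total_drop = v[i] - v[j]
            if total_drop > drop_tol:
                reports.append(
                    ArtifactReport(
                        well=curve.well,
                        kind="non-monotone-drop",
                        indices=tuple(range(i, j + 1)),
                        magnitude=float(total_drop),
                    )
                )
            i = j
        else:
            i += 1

    for k in range(1, n - 1):
        lo = max(v[k - 1], v[k + 1])
        if v[k] - v[k - 1] > drop_tol and v[k] - v[k + 1] > drop_tol:
            reports.append(
                ArtifactReport(
                    well=curve.well,
                    kind="transient-spike",
                    indices=(k,),
                    magnitude=float(v[k] - lo),
                )
            )
    return reports


def subtract_negative_control(plate: Plate, control: str = "A01") -> Plate:
    """Subtract the control well's curve from every other well.

    Off by default throughout the package (see module docstring); provided
    for users who explicitly want the vendor-recommended preprocessing.
    """
    control_label = WellCoordinate.from_label(control).label
    if control_label not in plate.curves:
        raise KeyError(f"control well {control_label} absent from plate")
    baseline = plate.curves[control_label].values
    curves = {}
    for label, curve in plate.curves.items():
        if label == control_label:
            curves[label] = curve
        else:
            curves[label] = replace(curve, values=curve.values - baseline)
    return Plate(curves, plate_id=plate.plate_id, dataset_id=plate.dataset_id)
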