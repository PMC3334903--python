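"""Core data model for 96-well Phenotype MicroArray kinetics.

A PM instrument records one respiration curve per well of an 8x12 plate:
color intensity in OmniLog units (effectively capped at 400) sampled on a
common time grid, typically every 15 minutes over ~91 hours.  The classes
here carry those curves plus the four shape parameters that the fitting
modules extract from them:

``lambda``  lag phase (hours) -- time before the main ascent,
``mu``      maximum slope (OmniLog units / hour),
``A``       maximum height (OmniLog units),
``AUC``     area under the curve (unit x hours for model/spline fits;
            a plain unit-sum for the native instrument algorithm).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "OMNILOG_CAP",
    "PLATE_ROWS",
    "PLATE_COLUMNS",
    "WellCoordinate",
    "KineticCurve",
    "Plate",
    "CurveParameters",
    "ParameterCI",
    "PARAMETER_NAMES",
]

#: Hard ceiling of the instrument's color scale, in OmniLog units.
OMNILOG_CAP = 400.0

PLATE_ROWS = "ABCDEFGH"
PLATE_COLUMNS = range(1, 13)

#: Canonical order of the four curve parameters.
PARAMETER_NAMES = ("lambda", "mu", "A", "AUC")

_LABEL_RE = re.compile(r"^([A-Ha-h])0?([1-9]|1[0-2])$")


@dataclass(frozen=True, order=True)
class WellCoordinate:
    """A well of the 8x12 plate, keyed canonically as e.g. ``"A01"``."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in PLATE_ROWS:
            raise ValueError(f"row must be one of {PLATE_ROWS!r}, got {self.row!r}")
        if self.column not in PLATE_COLUMNS:
            raise ValueError(f"column must be in 1..12, got {self.column!r}")

    @property
    def label(self) -> str:
        """Zero-padded canonical label, e.g. ``"A01"`` or ``"H12"``."""
        return f"{self.row}{self.column:02d}"

    @classmethod
    def from_label(cls, label: str) -> "WellCoordinate":
        """Parse ``"A1"`` or ``"A01"`` (case-insensitive) into a coordinate."""
        m = _LABEL_RE.match(label.strip())
        if m is None:
            raise ValueError(f"not a well label: {label!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    @classmethod
    def all_wells(cls) -> Iterator["WellCoordinate"]:
        """All 96 coordinates in plate order A01..A12, B01.., .., H12."""
        for row in PLATE_ROWS:
            for col in PLATE_COLUMNS:
                yield cls(row, col)


@dataclass
class KineticCurve:
    """One well's respiration time series plus experimental metadata.

    ``times`` are hours (strictly increasing), ``values`` OmniLog units on
    the same grid.  NaN values are tolerated in ``values`` (instrument
    dropouts); fitting code drops (time, value) pairs pairwise via
    :meth:`dropna`.
    """

    times: np.ndarray
    values: np.ndarray
    well: WellCoordinate
    strain: Optional[str] = None
    biological_replicate: Optional[str] = None
    technical_replicate: Optional[str] = None
    cultivation_hours: Optional[float] = None
    substrate: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.shape != self.values.shape:
            raise ValueError(
                f"length mismatch: {self.times.size} times vs {self.values.size} values"
            )
        if self.times.size < 4:
            raise ValueError(f"a curve needs >= 4 readings, got {self.times.size}")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.isinf(self.values)):
            raise ValueError("values must not be infinite")

    def __len__(self) -> int:
        return self.times.size

    def dropna(self) -> "KineticCurve":
        """Drop (time, value) pairs with missing values.

        Raises ``ValueError`` if fewer than 4 readings remain; callers that
        need an "unfittable" flag instead should catch it.
        """
        mask = np.isfinite(self.values)
        if mask.all():
            return self
        if mask.sum() < 4:
            raise ValueError(
                f"well {self.well.label}: only {int(mask.sum())} finite readings remain"
            )
        return replace(self, times=self.times[mask], values=self.values[mask])

    def equals(self, other: "KineticCurve") -> bool:
        return (
            self.well == other.well
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values, equal_nan=True)
            and self.strain == other.strain
            and self.biological_replicate == other.biological_replicate
            and self.technical_replicate == other.technical_replicate
            and self.cultivation_hours == other.cultivation_hours
            and self.substrate == other.substrate
        )


@dataclass
class Plate:
    """Up to 96 curves sharing one time grid."""

    curves: dict
    plate_id: Optional[str] = None
    dataset_id: Optional[str] = None

    def __post_init__(self) -> None:
        canonical = {}
        ref_times = None
        for key, curve in self.curves.items():
            coord = key if isinstance(key, WellCoordinate) else WellCoordinate.from_label(str(key))
            if coord.label in canonical:
                raise ValueError(f"duplicate curve for well {coord.label}")
            if curve.well != coord:
                raise ValueError(
                    f"curve keyed {coord.label} carries well {curve.well.label}"
                )
            if ref_times is None:
                ref_times = curve.times
            elif not np.array_equal(curve.times, ref_times):
                raise ValueError(
                    f"well {coord.label} does not share the plate's time grid"
                )
            canonical[coord.label] = curve
        self.curves = canonical

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self) -> Iterator[KineticCurve]:
        for label in sorted(self.curves):
            yield self.curves[label]

    def __getitem__(self, key) -> KineticCurve:
        if isinstance(key, WellCoordinate):
            key = key.label
        else:
            key = WellCoordinate.from_label(str(key)).label
        return self.curves[key]

    @property
    def times(self) -> np.ndarray:
        first = next(iter(self.curves.values()))
        return first.times

    @property
    def missing_wells(self) -> list:
        """Labels of the wells absent from this plate, in plate order."""
        return [w.label for w in WellCoordinate.all_wells() if w.label not in self.curves]

    def equals(self, other: "Plate") -> bool:
        if self.plate_id != other.plate_id or self.dataset_id != other.dataset_id:
            return False
        if set(self.curves) != set(other.curves):
            return False
        return all(self.curves[k].equals(other.curves[k]) for k in self.curves)


@dataclass
class CurveParameters:
    """The four shape parameters of one curve, with method provenance.

    Estimates judged biologically implausible (negative lag, A above the
    instrument cap) are *never* altered; they are recorded in ``flags`` and
    handled downstream, which is what makes the reliability accounting of
    the three estimation methods comparable.
    """

    lambda_: float
    mu: float
    A: float
    auc: float
    method: str  # "native" | "model" | "spline"
    model_name: Optional[str] = None
    fit_ok: bool = True
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.method not in {"native", "model", "spline"}:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.fit_ok:
            # An unfittable curve carries no usable parameters.
            self.lambda_ = math.nan
            self.mu = math.nan
            self.A = math.nan
            self.auc = math.nan
        self.flags = tuple(self.flags)

    def as_dict(self) -> dict:
        return {
            "lambda": self.lambda_,
            "mu": self.mu,
            "A": self.A,
            "AUC": self.auc,
        }

    def with_flags(self, *new_flags: str) -> "CurveParameters":
        merged = self.flags + tuple(f for f in new_flags if f not in self.flags)
        return replace(self, flags=merged)

    @property
    def implausible(self) -> bool:
        return ("lambda_negative" in self.flags) or ("A_above_cap" in self.flags)


@dataclass(frozen=True)
class ParameterCI:
    """Bootstrap percentile confidence interval for one curve parameter."""

    parameter: str
    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: Optional[int] = None
    n_failed: int = 0
    flags: tuple = ()

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")
        if np.isfinite(self.lower) and np.isfinite(self.upper) and self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")
        object.__setattr__(self, "flags", tuple(self.flags))

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper

    def shifted(self, c: float) -> "ParameterCI":
        return ParameterCI(
            self.parameter,
            self.point + c,
            self.lower + c,
            self.upper + c,
            self.level,
            self.n_boot,
            self.n_failed,
            self.flags,
        )
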