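"""Synthetic PM experiments: factorial designs and curve-shape taxonomy.

The generator reproduces the structure of real PM production runs --
strains x biological replicates x technical replicates x 96 wells, or a
cultivation-duration series -- and the taxonomy of curve shapes seen in
real plates: sigmoid positives, biphasic curves with an interim plateau,
near-flat negatives with slight linear drift, flat negatives, and
injected artifacts (transient spikes, dips).  Values are additive-Gaussian
noisy and truncated to the instrument range [0, 400].

Default time grid: 0 to 91 h in 0.25 h steps (365 readings), matching the
15-minute sampling of the instrument.  Everything is reproducible from a
single seed; replicate curves share their true shape but carry independent
noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Tuple, Union

import numpy as np

from .core import OMNILOG_CAP, KineticCurve, Plate, WellCoordinate
from .growth_models import evaluate_model

__all__ = [
    "SHAPE_FAMILIES",
    "ShapeSpec",
    "ExperimentDesign",
    "CurveSlot",
    "build_design",
    "default_time_grid",
    "simulate_curve",
    "simulate_experiment",
    "default_shape_policy",
    "dataset1_design",
    "single_run_design",
    "dataset3_design",
]

SHAPE_FAMILIES = (
    "logistic",
    "gompertz",
    "gompertz_exp",
    "richards",
    "biphasic",
    "linear_drift",
    "flat",
)

#: Default observation noise, OmniLog units (s.d. of the additive Gaussian
#: term).  Chosen to reproduce the visually smooth but clearly noisy
#: character of real respiration traces on a 0-400 unit scale.
DEFAULT_NOISE_SD = 3.0


def default_time_grid(t_max: float = 91.0, step: float = 0.25) -> np.ndarray:
    """The instrument grid: every 15 min over 91 h -> 365 readings."""
    n = int(round(t_max / step)) + 1
    return np.linspace(0.0, t_max, n)


@dataclass(frozen=True)
class ShapeSpec:
    """True shape of one simulated well.

    ``lambda_``/``mu``/``A`` are the sigmoid parameters (hours, units/h,
    units); family extras: ``nu`` (richards), ``alpha``/``t_shift``
    (gompertz_exp), ``second=(lambda2, mu2, A2)`` for the biphasic second
    phase, ``drift_slope`` (units/h) for near-flat drifting negatives and
    ``baseline`` for flat/drift families.  ``noise_df`` switches the noise
    to a (rescaled) Student t with that many degrees of freedom for
    heavier-tailed errors; default is Gaussian.
    """

    family: str
    lambda_: float = 10.0
    mu: float = 20.0
    A: float = 300.0
    nu: float = 2.0
    alpha: float = 0.05
    t_shift: float = 80.0
    second: Tuple[float, float, float] = (55.0, 5.0, 100.0)
    drift_slope: float = 0.3
    baseline: float = 15.0
    noise_sd: float = DEFAULT_NOISE_SD
    noise_df: Optional[float] = None
    spike: bool = False
    dip: bool = False
    cap: float = OMNILOG_CAP

    def __post_init__(self) -> None:
        if self.family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape family {self.family!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_df is not None and self.noise_df <= 2:
            raise ValueError("noise_df must exceed 2 (finite variance)")
        total_A = self.A + (self.second[2] if self.family == "biphasic" else 0.0)
        if self.family not in ("flat", "linear_drift") and total_A > self.cap:
            raise ValueError(f"A ({total_A}) exceeds the instrument cap {self.cap}")


def _true_curve(shape: ShapeSpec, times: np.ndarray) -> np.ndarray:
    f = shape.family
    if f in ("logistic", "gompertz"):
        return evaluate_model(f, times, {"A": shape.A, "mu": shape.mu, "lambda": shape.lambda_})
    if f == "richards":
        return evaluate_model(
            f, times, {"A": shape.A, "mu": shape.mu, "lambda": shape.lambda_, "nu": shape.nu}
        )
    if f == "gompertz_exp":
        return evaluate_model(
            f,
            times,
            {
                "A": shape.A,
                "mu": shape.mu,
                "lambda": shape.lambda_,
                "alpha": shape.alpha,
                "t_shift": shape.t_shift,
            },
        )
    if f == "biphasic":
        lam2, mu2, A2 = shape.second
        first = evaluate_model(
            "logistic", times, {"A": shape.A, "mu": shape.mu, "lambda": shape.lambda_}
        )
        second = evaluate_model("logistic", times, {"A": A2, "mu": mu2, "lambda": lam2})
        return first + second
    if f == "linear_drift":
        return shape.baseline + shape.drift_slope * times
    if f == "flat":
        return np.full_like(times, shape.baseline)
    raise ValueError(f"unknown shape family {f!r}")


def simulate_curve(
    shape: ShapeSpec,
    times: Optional[np.ndarray] = None,
    seed: Union[int, np.random.Generator, None] = None,
    well: WellCoordinate = WellCoordinate("A", 1),
    **metadata,
) -> KineticCurve:
    """Simulate one well: family curve + i.i.d. Gaussian noise, in [0, cap].

    With a fixed seed the output is reproducible bit-for-bit.  Artifact
    injection: ``spike`` raises one mid-curve reading by ~80 units,
    ``dip`` depresses a short run by ~40 units.
    """
    times = default_time_grid() if times is None else np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = _true_curve(shape, times).astype(float)
    if shape.noise_sd > 0:
        if shape.noise_df is None:
            noise = rng.normal(0.0, shape.noise_sd, size=times.size)
        else:
            # heavier-tailed option: Student t rescaled to the same s.d.
            df = shape.noise_df
            noise = rng.standard_t(df, size=times.size)
            noise *= shape.noise_sd / np.sqrt(df / (df - 2.0))
        v = v + noise
    if shape.spike:
        i = int(rng.integers(times.size // 4, 3 * times.size // 4))
        v[i] += 80.0
    if shape.dip:
        i = int(rng.integers(times.size // 4, 3 * times.size // 4))
        width = max(2, times.size // 60)
        v[i : i + width] -= 40.0
    v = np.clip(v, 0.0, shape.cap)
    return KineticCurve(times=times, values=v, well=well, **metadata)


# ---------------------------------------------------------------------------
# experimental designs


@dataclass(frozen=True)
class CurveSlot:
    """One curve's position in the factorial design."""

    strain: str
    biological_replicate: int
    cultivation_hours: Optional[float]
    technical_replicate: int
    well: WellCoordinate


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design: strains x biological reps x (durations x) technical reps x wells.

    ``technical_replicates`` is either a single count or one count per
    cultivation duration (a duration series may repeat some durations less
    often).  ``wells_per_plate`` is fixed at 96 for PM plates but kept
    explicit so the curve-count arithmetic is visible.
    """

    strains: Tuple[str, ...]
    biological_replicates: int = 1
    technical_replicates: Union[int, Tuple[int, ...]] = 1
    cultivation_durations: Optional[Tuple[float, ...]] = None
    wells_per_plate: int = 96

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        if self.cultivation_durations is not None:
            object.__setattr__(
                self, "cultivation_durations", tuple(self.cultivation_durations)
            )
        if isinstance(self.technical_replicates, int):
            if self.technical_replicates < 1:
                raise ValueError("technical_replicates must be positive")
        else:
            reps = tuple(self.technical_replicates)
            if self.cultivation_durations is None or len(reps) != len(
                self.cultivation_durations
            ):
                raise ValueError(
                    "per-level technical_replicates must match cultivation_durations"
                )
            if any(r < 1 for r in reps):
                raise ValueError("technical_replicates must be positive")
            object.__setattr__(self, "technical_replicates", reps)
        if not self.strains or self.biological_replicates < 1:
            raise ValueError("need >= 1 strain and >= 1 biological replicate")
        if self.wells_per_plate < 1 or self.wells_per_plate > 96:
            raise ValueError("wells_per_plate must be in 1..96")

    def _duration_reps(self) -> List[Tuple[Optional[float], int]]:
        if self.cultivation_durations is None:
            assert isinstance(self.technical_replicates, int)
            return [(None, self.technical_replicates)]
        if isinstance(self.technical_replicates, int):
            return [(d, self.technical_replicates) for d in self.cultivation_durations]
        return list(zip(self.cultivation_durations, self.technical_replicates))

    @property
    def n_plates(self) -> int:
        per_cell = sum(r for _, r in self._duration_reps())
        return len(self.strains) * self.biological_replicates * per_cell

    @property
    def n_curves(self) -> int:
        return self.n_plates * self.wells_per_plate

    @property
    def n_replicate_groups(self) -> int:
        """Design cells x wells (replicates of the same reaction)."""
        cells = len(self.strains) * self.biological_replicates * len(self._duration_reps())
        return cells * self.wells_per_plate


def build_design(design: ExperimentDesign) -> List[CurveSlot]:
    """Enumerate every curve slot of a design, deterministically ordered.

    The slot count equals the closed form
    ``sum over design cells of (technical reps x wells)``.
    """
    wells = list(WellCoordinate.all_wells())[: design.wells_per_plate]
    slots: List[CurveSlot] = []
    for strain in design.strains:
        for bio in range(1, design.biological_replicates + 1):
            for duration, reps in design._duration_reps():
                for tech in range(1, reps + 1):
                    for well in wells:
                        slots.append(
                            CurveSlot(
                                strain=strain,
                                biological_replicate=bio,
                                cultivation_hours=duration,
                                technical_replicate=tech,
                                well=well,
                            )
                        )
    assert len(slots) == design.n_curves
    return slots


def dataset1_design() -> ExperimentDesign:
    """4 strains x 2 biological x 10 technical x 96 wells = 7680 curves."""
    return ExperimentDesign(
        strains=("EC-K12", "EC-T", "PA-T", "PA-429SC"),
        biological_replicates=2,
        technical_replicates=10,
    )


def single_run_design(n_strains: int = 4) -> ExperimentDesign:
    """One production run: n strains x 10 technical x 96 wells (3840 for 4)."""
    return ExperimentDesign(
        strains=tuple(f"S{i+1}" for i in range(n_strains)),
        biological_replicates=1,
        technical_replicates=10,
    )


def dataset3_design() -> ExperimentDesign:
    """1 strain x 9 cultivation durations x (4,...,4,2) technical x 96 = 3264."""
    return ExperimentDesign(
        strains=("EC-K12",),
        biological_replicates=1,
        cultivation_durations=(16.75, 18.0, 19.33, 20.5, 21.92, 23.25, 24.5, 25.58, 40.33),
        technical_replicates=(4, 4, 4, 4, 4, 4, 4, 4, 2),
    )


# ---------------------------------------------------------------------------
# whole-experiment simulation

ShapePolicy = Union[Callable[[str, str], ShapeSpec], Mapping[Tuple[str, str], ShapeSpec]]


def default_shape_policy(
    seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD
) -> Callable[[str, str], ShapeSpec]:
    """A deterministic (strain, well) -> shape assignment mimicking real plates.

    Per strain: well A01 is a flat negative control; roughly 55% of wells
    are sigmoid positives (logistic/gompertz/richards with varied
    parameters), ~22% flat or drifting negatives, ~8% biphasic, and a few
    percent carry injected spike/dip artifacts.  The assignment depends
    only on ``seed``, the strain name and the well label, so replicate
    curves share their true shape.
    """

    def policy(strain: str, well_label: str) -> ShapeSpec:
        # crc32: stable across processes, unlike the builtin str hash
        key = np.random.SeedSequence(
            [seed, zlib.crc32(strain.encode()), zlib.crc32(well_label.encode())]
        )
        rng = np.random.default_rng(key)
        if well_label == "A01":
            return ShapeSpec(family="flat", baseline=12.0, noise_sd=noise_sd)
        u = rng.uniform()
        lam = float(rng.uniform(2.0, 20.0))
        mu = float(rng.uniform(5.0, 30.0))
        A = float(rng.uniform(150.0, 370.0))
        spike = bool(rng.uniform() < 0.03)
        dip = bool(rng.uniform() < 0.03)
        if u < 0.20:
            return ShapeSpec("logistic", lambda_=lam, mu=mu, A=A, noise_sd=noise_sd,
                             spike=spike, dip=dip)
        if u < 0.40:
            return ShapeSpec("gompertz", lambda_=lam, mu=mu, A=A, noise_sd=noise_sd,
                             spike=spike, dip=dip)
        if u < 0.55:
            return ShapeSpec("richards", lambda_=lam, mu=mu, A=A,
                             nu=float(rng.uniform(0.3, 4.0)), noise_sd=noise_sd,
                             spike=spike, dip=dip)
        if u < 0.63:
            A1 = float(rng.uniform(100.0, 200.0))
            return ShapeSpec(
                "biphasic",
                lambda_=lam,
                mu=mu,
                A=A1,
                second=(float(rng.uniform(45.0, 70.0)), float(rng.uniform(2.0, 8.0)),
                        float(rng.uniform(60.0, 150.0))),
                noise_sd=noise_sd,
                spike=spike,
                dip=dip,
            )
        if u < 0.78:
            return ShapeSpec(
                "linear_drift",
                baseline=float(rng.uniform(5.0, 30.0)),
                drift_slope=float(rng.uniform(0.05, 0.6)),
                noise_sd=noise_sd,
                spike=spike,
                dip=dip,
            )
        return ShapeSpec("flat", baseline=float(rng.uniform(5.0, 30.0)),
                         noise_sd=noise_sd, spike=spike, dip=dip)

    return policy


def simulate_experiment(
    design: ExperimentDesign,
    policy: Optional[ShapePolicy] = None,
    seed: Optional[int] = None,
    times: Optional[np.ndarray] = None,
) -> List[Plate]:
    """Simulate an entire design: one plate per design cell x technical replicate.

    ``policy`` maps ``(strain, well_label)`` to a :class:`ShapeSpec`
    (callable or mapping; a missing mapping key raises ``KeyError``).
    Identical (design, policy, seed) produce identical plates; replicate
    curves share the shape but have independent noise.
    """
    if policy is None:
        policy = default_shape_policy(seed=0)
    if isinstance(policy, Mapping):
        mapping = policy

        def policy_fn(strain: str, well: str) -> ShapeSpec:
            try:
                return mapping[(strain, well)]
            except KeyError:
                raise KeyError(f"shape policy has no entry for ({strain!r}, {well!r})")

    else:
        policy_fn = policy

    times = default_time_grid() if times is None else np.asarray(times, dtype=float)
    slots = build_design(design)
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(len(slots))

    plates: Dict[Tuple, Plate] = {}
    current: Dict[Tuple, Dict[str, KineticCurve]] = {}
    for slot, child in zip(slots, children):
        key = (slot.strain, slot.biological_replicate, slot.cultivation_hours,
               slot.technical_replicate)
        shape = policy_fn(slot.strain, slot.well.label)
        rng = np.random.default_rng(child)
        curve = simulate_curve(
            shape,
            times=times,
            seed=rng,
            well=slot.well,
            strain=slot.strain,
            biological_replicate=str(slot.biological_replicate),
            technical_replicate=str(slot.technical_replicate),
            cultivation_hours=slot.cultivation_hours,
        )
        current.setdefault(key, {})[slot.well.label] = curve

    out: List[Plate] = []
    for key, curves in current.items():
        strain, bio, duration, tech = key
        parts = [strain, f"b{bio}"]
        if duration is not None:
            parts.append(f"d{duration:g}")
        parts.append(f"t{tech}")
        out.append(Plate(curves, plate_id="-".join(parts)))
    return out
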