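import numpy as np
import pytest

import pmkinetics as pm


@pytest.fixture
def grid():
    """Coarse 1-h observation grid over 91 h (92 readings)."""
    return pm.default_time_grid(91.0, 1.0)


@pytest.fixture
def dense_grid():
    """The instrument's 15-min grid (365 readings)."""
    return pm.default_time_grid()


@pytest.fixture
def logistic_curve(grid):
    """Noiseless logistic positive: lambda=10 h, mu=20 u/h, A=300 u."""
    return pm.simulate_curve(
        pm.ShapeSpec("logistic", lambda_=10.0, mu=20.0, A=300.0, noise_sd=0.0),
        grid,
        seed=0,
    )


@pytest.fixture
def noisy_logistic_curve(grid):
    return pm.simulate_curve(
        pm.ShapeSpec("logistic", lambda_=10.0, mu=20.0, A=300.0, noise_sd=3.0),
        grid,
        seed=7,
    )


@pytest.fixture
def flat_curve(grid):
    return pm.simulate_curve(
        pm.ShapeSpec("flat", baseline=12.0, noise_sd=0.0), grid, seed=0
    )


@pytest.fixture
def drift_curve(grid):
    """Near-flat negative with slight linear color drift + noise."""
    return pm.simulate_curve(
        pm.ShapeSpec("linear_drift", baseline=10.0, drift_slope=0.3, noise_sd=2.0),
        grid,
        seed=3,
    )


@pytest.fixture
def biphasic_curve(grid):
    """Steep first ascent, interim plateau, shallower second ascent."""
    return pm.simulate_curve(
        pm.ShapeSpec(
            "biphasic",
            lambda_=5.0,
            mu=25.0,
            A=150.0,
            second=(55.0, 5.0, 100.0),
            noise_sd=0.0,
        ),
        grid,
        seed=0,
    )


@pytest.fixture
def tiny_plate(grid):
    """A 3-well plate with heterogeneous shapes."""
    curves = {}
    for label, fam in [("A01", "flat"), ("A02", "logistic"), ("A03", "linear_drift")]:
        well = pm.WellCoordinate.from_label(label)
        spec = pm.ShapeSpec(fam, lambda_=8.0, mu=15.0, A=250.0, noise_sd=1.0)
        curves[label] = pm.simulate_curve(
            spec, grid, seed=hash(label) % 1000, well=well, strain="S1"
        )
    return pm.Plate(curves, plate_id="P1", dataset_id="D1")
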