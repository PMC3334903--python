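"""Bootstrap CIs, overlap logic, group means and simultaneous comparisons."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pmkinetics as pm
from pmkinetics.uncertainty import all_pairs_contrasts, vs_control_contrasts


class TestBootstrapCIs:
    def test_noiseless_line_gives_zero_width_intervals(self):
        """Every resample refits the same line, whatever the seed."""
        t = np.linspace(0.0, 10.0, 30)
        curve = pm.KineticCurve(times=t, values=3.0 * t, well=pm.WellCoordinate("A", 1))
        cis = pm.bootstrap_cis(curve, method="spline", B=50, seed=123)
        for name in ("lambda", "mu", "A", "AUC"):
            assert cis[name].width < 1e-6, name

    def test_seeded_determinism(self, noisy_logistic_curve):
        a = pm.bootstrap_cis(noisy_logistic_curve, method="spline", B=20, seed=5)
        b = pm.bootstrap_cis(noisy_logistic_curve, method="spline", B=20, seed=5)
        c = pm.bootstrap_cis(noisy_logistic_curve, method="spline", B=20, seed=6)
        for name in a:
            assert a[name].lower == b[name].lower
            assert a[name].upper == b[name].upper
        assert any(a[n].lower != c[n].lower for n in a)

    def test_flat_noise_curve_has_broad_lag_and_slope_cis(self, grid):
        """Drifting negatives yield much broader lambda/mu intervals than a
        clean sigmoid -- the uncertainty the spline reports on non-reactions."""
        sigmoid = pm.simulate_curve(
            pm.ShapeSpec("logistic", lambda_=10.0, mu=20.0, A=300.0, noise_sd=2.0),
            grid,
            seed=1,
        )
        drifty = pm.simulate_curve(
            pm.ShapeSpec("linear_drift", baseline=10.0, drift_slope=0.2, noise_sd=2.0),
            grid,
            seed=2,
        )
        ci_sig = pm.bootstrap_cis(sigmoid, method="spline", B=60, seed=9)
        ci_neg = pm.bootstrap_cis(drifty, method="spline", B=60, seed=9)
        assert ci_neg["lambda"].width > 3 * ci_sig["lambda"].width

    def test_model_method_works_and_reports_failures(self, noisy_logistic_curve):
        cis = pm.bootstrap_cis(
            noisy_logistic_curve, method="model", model_name="logistic", B=30, seed=2
        )
        assert cis["A"].n_failed <= 30
        assert cis["A"].lower <= cis["A"].point <= cis["A"].upper

    def test_unfittable_curve_raises(self, grid):
        flat_zero = pm.KineticCurve(
            times=grid, values=np.zeros(grid.size), well=pm.WellCoordinate("A", 1)
        )
        with pytest.raises(ValueError, match="not fittable"):
            pm.bootstrap_cis(flat_zero, method="model", model_name="logistic", B=10, seed=0)


def _ci(lo, hi, parameter="A", level=0.95):
    return pm.ParameterCI(parameter, (lo + hi) / 2, lo, hi, level=level)


class TestCIOverlap:
    @pytest.mark.parametrize(
        "a,b,overlaps,gap",
        [
            ((1.0, 2.0), (3.0, 4.0), False, 1.0),
            ((3.0, 4.0), (1.0, 2.0), False, -1.0),
            ((1.0, 3.0), (2.0, 4.0), True, 0.0),
            ((1.0, 2.0), (2.0, 3.0), True, 0.0),   # shared endpoint: overlap
            ((0.0, 10.0), (2.0, 3.0), True, 0.0),  # containment
            ((1.0, 1.0), (1.0, 1.0), True, 0.0),   # degenerate points
        ],
    )
    def test_interval_arithmetic_cases(self, a, b, overlaps, gap):
        res = pm.ci_overlap_minimum_difference(_ci(*a), _ci(*b))
        assert res.overlaps == overlaps
        assert res.min_expected_difference == pytest.approx(gap)

    def test_exhaustive_small_grid(self):
        """All interval pairs on a small integer grid match the definition."""
        endpoints = [
            (lo, hi) for lo, hi in itertools.product(range(5), repeat=2) if lo <= hi
        ]
        for a, b in itertools.product(endpoints, repeat=2):
            res = pm.ci_overlap_minimum_difference(_ci(*a), _ci(*b))
            expected_overlap = a[0] <= b[1] and b[0] <= a[1]
            assert res.overlaps == expected_overlap
            if expected_overlap:
                assert res.min_expected_difference == 0.0
            elif b[0] > a[1]:
                assert res.min_expected_difference == b[0] - a[1]
            else:  # a lies above b: gap reported with negative sign (b - a)
                assert res.min_expected_difference == -(a[0] - b[1])

    @given(
        st.tuples(st.floats(-50, 50), st.floats(0, 20)),
        st.tuples(st.floats(-50, 50), st.floats(0, 20)),
        st.floats(-30, 30),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetric_and_translation_invariant(self, a, b, shift):
        # quantize so interval gaps stay resolvable after translation
        a = (round(a[0], 3), round(a[1], 3))
        b = (round(b[0], 3), round(b[1], 3))
        shift = round(shift, 3)
        ci_a = _ci(a[0], a[0] + a[1])
        ci_b = _ci(b[0], b[0] + b[1])
        fwd = pm.ci_overlap_minimum_difference(ci_a, ci_b)
        rev = pm.ci_overlap_minimum_difference(ci_b, ci_a)
        assert fwd.overlaps == rev.overlaps
        assert fwd.min_expected_difference == pytest.approx(
            -rev.min_expected_difference, abs=1e-9
        )
        moved = pm.ci_overlap_minimum_difference(ci_a.shifted(shift), ci_b.shifted(shift))
        assert moved.overlaps == fwd.overlaps
        assert moved.min_expected_difference == pytest.approx(
            fwd.min_expected_difference, abs=1e-6
        )

    def test_mismatched_parameter_or_level_rejected(self):
        with pytest.raises(ValueError, match="parameter"):
            pm.ci_overlap_minimum_difference(_ci(0, 1, "A"), _ci(0, 1, "mu"))
        with pytest.raises(ValueError, match="level"):
            pm.ci_overlap_minimum_difference(_ci(0, 1), _ci(0, 1, level=0.9))


class TestGroupMeanCIs:
    def test_single_member_group_is_identity(self):
        member = pm.ParameterCI("mu", 5.0, 4.0, 6.0)
        out = pm.group_mean_cis({"g": [member]})["g"]
        assert (out.point, out.lower, out.upper) == (5.0, 4.0, 6.0)

    def test_two_member_arithmetic(self):
        members = [
            pm.ParameterCI("A", 1.0, 0.0, 2.0),
            pm.ParameterCI("A", 3.0, 2.0, 4.0),
        ]
        out = pm.group_mean_cis({"g": members})["g"]
        assert out.point == 2.0
        assert (out.lower, out.upper) == (1.0, 3.0)
        assert "mean_of_cis" in out.flags  # marked as the visualization device

    def test_random_groups_match_averaging_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 8))
            members = [
                pm.ParameterCI("AUC", float(p), float(p - w), float(p + w))
                for p, w in zip(rng.normal(size=n), rng.uniform(0.1, 2, size=n))
            ]
            out = pm.group_mean_cis({"g": members})["g"]
            assert out.point == pytest.approx(np.mean([m.point for m in members]))
            assert out.lower == pytest.approx(np.mean([m.lower for m in members]))
            assert out.upper == pytest.approx(np.mean([m.upper for m in members]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pm.group_mean_cis({"g": []})


class TestSimultaneousComparisons:
    def test_single_contrast_reduces_to_pooled_t_interval(self):
        rng = np.random.default_rng(42)
        g1 = rng.normal(10.0, 2.0, size=8)
        g2 = rng.normal(12.0, 2.0, size=10)
        comp = pm.simultaneous_mean_differences(
            {"a": g1, "b": g2}, contrasts=np.array([[-1.0, 1.0]]), seed=0,
            n_draws=200_000,
        )
        n1, n2 = len(g1), len(g2)
        df = n1 + n2 - 2
        s2 = ((g1 - g1.mean()) ** 2).sum() + ((g2 - g2.mean()) ** 2).sum()
        s2 /= df
        se = math.sqrt(s2 * (1 / n1 + 1 / n2))
        tcrit = stats.t.ppf(0.975, df)
        assert comp.estimates[0] == pytest.approx(g2.mean() - g1.mean())
        assert comp.critical_value == pytest.approx(tcrit, rel=0.005)
        assert comp.lower[0] == pytest.approx(
            g2.mean() - g1.mean() - tcrit * se, rel=0.01
        )

    def test_null_familywise_coverage(self):
        """Identical groups: all intervals contain 0 in >= 93% of runs."""
        rng = np.random.default_rng(7)
        # one shared critical value per contrast structure (same sizes/df)
        ok = 0
        runs = 200
        for _ in range(runs):
            groups = {f"g{i}": rng.normal(0.0, 1.0, size=5) for i in range(4)}
            comp = pm.simultaneous_mean_differences(
                groups, contrasts="all-pairs", seed=11, n_draws=20_000
            )
            ok += not comp.significant.any()
        assert ok >= 0.93 * runs

    def test_planted_shift_flagged_only_for_shifted_group(self):
        rng = np.random.default_rng(3)
        sigma = 1.0
        groups = {f"g{i}": rng.normal(0.0, sigma, size=6) for i in range(9)}
        groups["g4"] = groups["g4"] + 5.0 * sigma
        comp = pm.simultaneous_mean_differences(
            groups, contrasts="all-pairs", seed=5, n_draws=50_000
        )
        labels = comp.groups
        for row, sig in zip(comp.contrasts, comp.significant):
            involved = {labels[j] for j in np.nonzero(row)[0]}
            assert sig == ("g4" in involved)

    def test_simultaneous_at_least_as_wide_as_unadjusted_t(self):
        rng = np.random.default_rng(9)
        groups = {f"g{i}": rng.normal(0.0, 1.0, size=6) for i in range(5)}
        comp = pm.simultaneous_mean_differences(groups, seed=2, n_draws=50_000)
        t_unadj = stats.t.ppf(0.975, comp.df)
        assert comp.critical_value >= t_unadj - 1e-6

    def test_contrast_row_not_summing_to_zero_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            pm.simultaneous_mean_differences(
                {"a": [1.0, 2.0], "b": [2.0, 3.0]},
                contrasts=np.array([[1.0, -1.0], [1.0, 1.0]]),
                seed=0,
            )

    def test_contrast_helpers(self):
        C = all_pairs_contrasts(4)
        assert C.shape == (6, 4)
        assert np.allclose(C.sum(axis=1), 0.0)
        D = vs_control_contrasts(4)
        assert D.shape == (3, 4)
        assert np.all(D[:, 0] == -1.0)

    def test_needs_residual_degrees_of_freedom(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            pm.simultaneous_mean_differences({"a": [1.0], "b": [2.0]}, seed=0)
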