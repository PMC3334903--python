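"""Reaction calls, lag truncation, archetypal analysis, rank correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pmkinetics as pm


class TestReactionCall:
    @pytest.mark.parametrize(
        "A,expected",
        [
            (150.0, "positive"),
            (100.0, "negative"),   # strictly greater than the threshold
            (100.0001, "positive"),
            (0.0, "negative"),
        ],
    )
    def test_threshold_rule(self, A, expected):
        assert pm.call_reaction(A) == expected

    def test_missing_A_gives_no_call(self):
        assert pm.call_reaction(float("nan")) is None
        unfittable = pm.CurveParameters(
            math.nan, math.nan, math.nan, math.nan, method="spline", fit_ok=False
        )
        assert pm.call_reaction(unfittable) is None

    def test_custom_threshold(self):
        assert pm.call_reaction(150.0, threshold=200.0) == "negative"


class TestTruncateLambda:
    def test_direct_application(self):
        out = pm.truncate_lambda([-500.0, -2.0, 5.0, 10.0])
        np.testing.assert_array_equal(out, [-10.0, -2.0, 5.0, 10.0])

    def test_values_within_band_unchanged(self):
        vals = np.array([-9.0, 0.0, 3.0, 10.0])
        np.testing.assert_array_equal(pm.truncate_lambda(vals), vals)

    def test_idempotent_and_matches_clamping_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            vals = rng.normal(0, 50, size=rng.integers(2, 30))
            out = pm.truncate_lambda(vals)
            M = vals.max()
            np.testing.assert_array_equal(out, np.where(vals < -M, -M, vals))
            np.testing.assert_array_equal(pm.truncate_lambda(out), out)

    def test_nan_preserved(self):
        out = pm.truncate_lambda([np.nan, -100.0, 4.0])
        assert math.isnan(out[0])
        assert out[1] == -4.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="no finite"):
            pm.truncate_lambda([np.nan, np.nan])


def _planted_vertices(n=300, noise=0.01, seed=0):
    """Points concentrated at 3 simplex vertices in 4-d parameter space."""
    rng = np.random.default_rng(seed)
    V = np.array(
        [
            [2.0, 25.0, 320.0, 21000.0],
            [30.0, 6.0, 150.0, 8000.0],
            [-5.0, 0.5, 20.0, 1500.0],
        ]
    )
    idx = rng.integers(0, 3, size=n)
    X = V[idx] + rng.normal(0, noise, size=(n, 4)) * V.std(axis=0)
    return X, V


class TestArchetypes:
    def test_single_archetype_is_the_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5.0, 2.0, size=(80, 4))
        model = pm.fit_archetypes(X, k=1, seed=0)
        np.testing.assert_allclose(model.archetypes[0], X.mean(axis=0), atol=1e-6)
        # RSS on the standardized fitting scale equals the centered SS there
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        assert model.rss == pytest.approx(((Xs - Xs.mean(axis=0)) ** 2).sum(), rel=1e-6)

    def test_planted_vertices_recovered(self):
        X, V = _planted_vertices()
        model = pm.fit_archetypes(X, k=3, seed=3, n_restarts=5)
        # match each true vertex to the nearest recovered archetype
        scale = X.std(axis=0)
        for v in V:
            d = np.min(np.linalg.norm((model.archetypes - v) / scale, axis=1))
            assert d < 0.2

    def test_coefficients_on_simplex(self):
        X, _ = _planted_vertices(n=120)
        model = pm.fit_archetypes(X, k=3, seed=1)
        C = model.coefficients
        assert np.all(C >= -1e-8)
        np.testing.assert_allclose(C.sum(axis=1), 1.0, atol=1e-8)
        B = model.weights
        assert np.all(B >= -1e-8)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-8)

    def test_rss_trace_non_increasing(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(100, 4))
        for k in (2, 4):
            model = pm.fit_archetypes(X, k=k, seed=7)
            assert np.all(np.diff(model.rss_path) <= 1e-9)

    def test_archetypes_are_convex_combinations_of_data(self):
        X, _ = _planted_vertices(n=60)
        model = pm.fit_archetypes(X, k=2, seed=2)
        recon = model.weights @ X
        # weights act on raw data only after the same standardization;
        # verify on the standardized scale instead
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Xs = (X - mu) / sd
        recon_std = model.weights @ Xs
        np.testing.assert_allclose(
            recon_std, (model.archetypes - mu) / sd, atol=1e-6
        )

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError, match="n_archetypes"):
            pm.fit_archetypes(np.zeros((3, 2)), k=5)

    def test_transform_new_data(self):
        X, _ = _planted_vertices(n=90)
        est = pm.ArchetypalAnalysis(n_archetypes=3, random_state=0).fit(X)
        coeffs = est.transform(X[:10])
        assert coeffs.shape == (10, 3)
        np.testing.assert_allclose(coeffs.sum(axis=1), 1.0, atol=1e-8)


class TestElbowSelection:
    def test_planted_three_vertex_data_select_k3(self):
        X, _ = _planted_vertices()
        result = pm.step_archetypes_elbow(X, k_range=range(1, 7), restarts=5, seed=0)
        assert result.selected_k == 3

    def test_scree_deterministic_under_same_seed(self):
        X, _ = _planted_vertices(n=80)
        r1 = pm.step_archetypes_elbow(X, k_range=range(1, 5), restarts=3, seed=5)
        r2 = pm.step_archetypes_elbow(X, k_range=range(1, 5), restarts=3, seed=5)
        assert r1.rss == r2.rss
        assert r1.selected_k == r2.selected_k

    def test_unstructured_blob_selects_dominating_early_drop(self):
        """A single Gaussian blob has no planted vertex structure: the
        selected drop must dominate every later drop."""
        rng = np.random.default_rng(33)
        X = rng.normal(size=(150, 4))
        result = pm.step_archetypes_elbow(X, k_range=range(1, 6), restarts=3, seed=1)
        sel = result.selected_k
        later = [result.drops[k] for k in result.drops if k > sel]
        if later:
            assert result.drops[sel] > max(later)

    def test_best_rss_non_increasing_in_k_on_planted_data(self):
        X, _ = _planted_vertices(n=150)
        result = pm.step_archetypes_elbow(X, k_range=range(1, 6), restarts=5, seed=2)
        rss = [result.rss[k] for k in result.k_values]
        # restart jitter at the noise floor is bounded by 0.01% of the scale
        tol = 1e-4 * rss[0]
        assert all(b <= a + tol for a, b in zip(rss, rss[1:]))


class TestParameterCorrelations:
    @staticmethod
    def _toy_table():
        return pd.DataFrame(
            {
                "model_lambda": [1.0, 2.0, 3.0, 4.0, 5.0],
                "model_mu": [2.0, 1.0, 4.0, 3.0, 5.0],
                "spline_lambda": [1.1, 2.2, 2.9, 4.2, 5.1],
                "spline_mu": [5.0, 4.0, 3.0, 2.0, 1.0],
            }
        )

    def test_self_correlation_is_one(self):
        corr = pm.parameter_correlations(self._toy_table(), method="spearman")
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)

    def test_monotone_invariance(self):
        x = np.linspace(0.1, 3.0, 20)
        table = pd.DataFrame({"x": x, "expx": np.exp(x)})
        for method in ("spearman", "kendall"):
            corr = pm.parameter_correlations(table, method=method)
            assert corr.loc["x", "expx"] == pytest.approx(1.0)

    def test_toy_table_matches_brute_force_oracles(self):
        table = self._toy_table()
        x = table["model_lambda"].to_numpy()
        y = table["model_mu"].to_numpy()
        n = len(x)
        # Kendall: literal pair counting
        conc = disc = 0
        for i in range(n):
            for j in range(i + 1, n):
                s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
                conc += s > 0
                disc += s < 0
        tau = (conc - disc) / (n * (n - 1) / 2)
        got_k = pm.parameter_correlations(table, method="kendall")
        assert got_k.loc["model_lambda", "model_mu"] == pytest.approx(tau)
        # Spearman: Pearson correlation of the ranks
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        rho = np.corrcoef(rx, ry)[0, 1]
        got_s = pm.parameter_correlations(table, method="spearman")
        assert got_s.loc["model_lambda", "model_mu"] == pytest.approx(rho)

    def test_constant_column_reported_missing(self):
        table = self._toy_table()
        table["const"] = 7.0
        corr = pm.parameter_correlations(table)
        assert math.isnan(corr.loc["const", "model_mu"])

    def test_too_few_complete_rows_rejected(self):
        table = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, np.nan]})
        with pytest.raises(ValueError, match="complete rows"):
            pm.parameter_correlations(table)
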