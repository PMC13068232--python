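"""GLM fitting, spline bases, screening, forward selection and forests."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from malnupred import modeling as m
from malnupred.synthetic_data import simulate_logistic_table


def _binary_table(n=100, events=30):
    y = np.zeros(n, dtype=int)
    y[:events] = 1
    return pd.DataFrame({"y": y})


class TestFitGlm:
    def test_intercept_only_binomial_closed_form(self):
        fit = m.fit_glm(_binary_table(), m.ModelSpec("y", "binomial", []))
        assert fit.params["intercept"] == pytest.approx(np.log(30 / 70), abs=1e-6)
        # AIC = -2*(30 ln .3 + 70 ln .7) + 2
        expected = -2 * (30 * np.log(0.3) + 70 * np.log(0.7)) + 2
        assert fit.aic == pytest.approx(expected, abs=1e-6)

    def test_intercept_only_gaussian_is_mean(self):
        df = pd.DataFrame({"y": [-1.0, -2.0, -3.0]})
        fit = m.fit_glm(df, m.ModelSpec("y", "gaussian", []))
        assert fit.params["intercept"] == pytest.approx(-2.0)
        # Gaussian AIC counts the variance parameter
        n, rss = 3, 2.0
        llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        assert fit.aic == pytest.approx(-2 * llf + 2 * 2, abs=1e-9)

    def test_irls_matches_derivative_free_oracle(self):
        """IRLS logistic coefficients vs Nelder-Mead likelihood maximiser."""
        df = simulate_logistic_table({"intercept": -0.5, "x1": 0.8, "x2": -0.4},
                                     n=800, seed=11)
        spec = m.ModelSpec("y", "binomial", [m.Term("x1"), m.Term("x2")])
        fit = m.fit_glm(df, spec)
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        y = df["y"].to_numpy()

        def negll(beta):
            p = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
            return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        oracle = minimize(negll, np.zeros(3), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert np.allclose(fit.params.to_numpy(), oracle.x, atol=1e-4)

    def test_nesting_never_hurts_loglik(self):
        df = simulate_logistic_table({"intercept": 0.0, "x1": 0.5}, n=500, seed=3)
        small = m.fit_glm(df, m.ModelSpec("y", "binomial", []))
        big = m.fit_glm(df, m.ModelSpec("y", "binomial", [m.Term("x1")]))
        assert big.loglik >= small.loglik - 1e-9

    def test_more_params_than_rows_rejected(self):
        df = pd.DataFrame({"y": [0, 1], "x1": [0.0, 1.0], "x2": [1.0, 0.0]})
        with pytest.raises(ValueError):
            m.fit_glm(df, m.ModelSpec("y", "binomial", [m.Term("x1"), m.Term("x2")]))

    def test_parameter_recovery_large_n(self):
        beta = {"intercept": -1.5, "x1": 0.7, "x2": -0.5}
        df = simulate_logistic_table(beta, n=20000, seed=42)
        fit = m.fit_glm(
            df, m.ModelSpec("y", "binomial", [m.Term("x1"), m.Term("x2")])
        )
        # rough SE ~ 1/sqrt(n * p(1-p)): comfortably within 3 SE at this n
        assert fit.params["intercept"] == pytest.approx(beta["intercept"], abs=0.12)
        assert fit.params["x1"] == pytest.approx(beta["x1"], abs=0.12)
        assert fit.params["x2"] == pytest.approx(beta["x2"], abs=0.12)


class TestSplineBasis:
    def test_deterministic_and_df_columns(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 200)
        basis = m.SplineBasis(df=4).fit(x)
        B1 = basis.transform(x)
        B2 = basis.transform(x)
        assert B1.shape == (200, 4)
        assert np.array_equal(B1, B2)

    def test_linear_function_in_span(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 300)
        B = np.column_stack([np.ones(len(x)), m.SplineBasis(df=5).fit_transform(x)])
        target = 2.0 + 3.0 * x
        coef, _, _, _ = np.linalg.lstsq(B, target, rcond=None)
        assert np.max(np.abs(B @ coef - target)) < 1e-8

    def test_out_of_range_clamps(self):
        x = np.linspace(0, 1, 50)
        basis = m.SplineBasis(df=4).fit(x)
        hi = basis.transform(np.array([2.0]))
        at_edge = basis.transform(np.array([1.0]))
        assert np.allclose(hi, at_edge)

    def test_insufficient_distinct_values(self):
        with pytest.raises(ValueError):
            m.SplineBasis(df=4).fit(np.array([1.0, 1.0, 2.0]))


class TestScreening:
    def test_true_predictor_ranks_first(self):
        df = simulate_logistic_table({"intercept": -1.0, "signal": 0.9},
                                     n=5000, seed=5, n_noise=3)
        scr = m.univariate_screen(
            df, "y", "binomial",
            {"signal": ["signal"], "noise1": ["noise1"], "noise2": ["noise2"],
             "noise3": ["noise3"]},
        )
        assert scr.table.iloc[0]["predictor"] == "signal"

    def test_tie_broken_alphabetically(self):
        df = simulate_logistic_table({"intercept": 0.0, "x1": 0.5}, n=400, seed=6)
        df["aaa"] = df["x1"]
        df["bbb"] = df["x1"]
        scr = m.univariate_screen(df, "y", "binomial",
                                  {"aaa": ["aaa"], "bbb": ["bbb"]})
        assert list(scr.table["predictor"]) == ["aaa", "bbb"]

    def test_constant_predictor_excluded(self):
        df = simulate_logistic_table({"intercept": 0.0, "x1": 0.5}, n=200, seed=7)
        df["flat"] = 1.0
        scr = m.univariate_screen(df, "y", "binomial",
                                  {"x1": ["x1"], "flat": ["flat"]})
        assert "flat" in scr.excluded
        assert list(scr.table["predictor"]) == ["x1"]

    def test_window_choice_by_aic(self):
        df = simulate_logistic_table({"intercept": -1.0, "good": 0.8},
                                     n=3000, seed=8, n_noise=1)
        scr = m.univariate_screen(df, "y", "binomial",
                                  {"pred": ["good", "noise1"]})
        assert scr.table.iloc[0]["column"] == "good"


class TestCorrelationScreen:
    def test_self_and_monotone_pairs_blocked(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=1000)
        df = pd.DataFrame({"x": x, "expx": np.exp(x), "indep": rng.normal(size=1000)})
        corr, blocked = m.correlation_screen(df)
        assert frozenset(("x", "expx")) in blocked  # Spearman rank invariance
        assert frozenset(("x", "indep")) not in blocked
        assert abs(corr.loc["x", "indep"]) < 0.1


class TestForwardSelect:
    def test_recovers_true_predictors(self):
        df = simulate_logistic_table(
            {"intercept": -1.2, "x1": 0.8, "x2": -0.6}, n=5000, seed=10, n_noise=6
        )
        cand = {c: [c] for c in ["x1", "x2"] + [f"noise{i}" for i in range(1, 7)]}
        scr = m.univariate_screen(df, "y", "binomial", cand)
        spec, trace = m.forward_select(scr, set(), df, "y", "binomial",
                                       smoothable=set())
        names = {t.name for t in spec.terms}
        assert {"x1", "x2"} <= names

    def test_blocked_pair_skipped(self):
        df = simulate_logistic_table({"intercept": -1.0, "x1": 0.8},
                                     n=2000, seed=12, n_noise=1)
        df["x1copy"] = df["x1"] + 1e-9
        cand = {c: [c] for c in ["x1", "x1copy", "noise1"]}
        scr = m.univariate_screen(df, "y", "binomial", cand)
        _, blocked = m.correlation_screen(df[["x1", "x1copy", "noise1"]])
        spec, trace = m.forward_select(scr, blocked, df, "y", "binomial",
                                       smoothable=set())
        names = {t.name for t in spec.terms}
        assert not ({"x1", "x1copy"} <= names)
        assert (trace["action"] == "skipped_blocked").any()

    def test_all_noise_returns_intercept_only(self):
        df = simulate_logistic_table({"intercept": 0.0}, n=300, seed=1, n_noise=3)
        cand = {f"noise{i}": [f"noise{i}"] for i in range(1, 4)}
        scr = m.univariate_screen(df, "y", "binomial", cand)
        spec, _ = m.forward_select(scr, set(), df, "y", "binomial", smoothable=set())
        assert spec.terms == []


class TestForest:
    def test_probabilities_in_unit_interval_and_deterministic(self):
        df = simulate_logistic_table({"intercept": -0.5, "x1": 1.0},
                                     n=400, seed=14, n_noise=1)
        spec = m.ForestSpec(n_trees=50, max_split_vars=2, seed=99)
        f1 = m.fit_forest(df, "y", ["x1", "noise1"], spec)
        f2 = m.fit_forest(df, "y", ["x1", "noise1"], spec)
        p1, p2 = f1.predict(df), f2.predict(df)
        assert np.all((p1 >= 0) & (p1 <= 1))
        assert np.array_equal(p1, p2)

    def test_single_deep_tree_fits_separable_data(self):
        # noiseless separable data: one unrestricted tree reproduces training labels
        x = np.linspace(-2, 2, 200)
        df = pd.DataFrame({"x": x, "y": (x > 0).astype(int)})
        spec = m.ForestSpec(n_trees=1, max_split_vars=1, seed=0, bootstrap=False)
        f = m.fit_forest(df, "y", ["x"], spec)
        assert np.allclose(f.predict(df), df["y"])

    def test_unseen_category_raises_coverage_error(self):
        df = pd.DataFrame(
            {"y": [0, 1] * 20, "cat": [1.0, 2.0] * 20}
        )
        f = m.fit_forest(df, "y", ["cat"], m.ForestSpec(n_trees=10, seed=1),
                         categorical=["cat"])
        new = pd.DataFrame({"cat": [3.0]})
        with pytest.raises(m.CoverageError):
            f.predict(new)

    def test_forest_beats_intercept_glm_on_nonlinear_signal(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(-3, 3, 1500)
        y = np.sin(x) * 2 + rng.normal(0, 0.1, 1500)
        df = pd.DataFrame({"x": x, "y": y})
        forest = m.fit_forest(df, "y", ["x"],
                              m.ForestSpec(n_trees=100, max_split_vars=1,
                                           task="regression", seed=2))
        glm = m.fit_glm(df, m.ModelSpec("y", "gaussian", []))
        mae_f = np.mean(np.abs(forest.predict(df) - y))
        mae_g = np.mean(np.abs(glm.predict(df) - y))
        assert mae_f < mae_g


class TestPredictStratum:
    def test_mean_of_child_predictions(self):
        class Dummy:
            def predict(self, rows):
                return np.full(len(rows), 0.2)

        rows = pd.DataFrame({"x": [1, 2, 3]})
        assert m.predict_stratum(Dummy(), rows) == pytest.approx(0.2)

    def test_intercept_only_predicts_training_prevalence(self):
        df = _binary_table(100, 30)
        fit = m.fit_glm(df, m.ModelSpec("y", "binomial", []))
        assert m.predict_stratum(fit, df) == pytest.approx(0.3, abs=1e-8)
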