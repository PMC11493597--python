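"""Lasso correctness against independent oracles, LOSO-CV, metrics."""

import numpy as np
import pandas as pd
import pytest

from vgrf.modeling import (
    DEFAULT_LAMBDA_GRID,
    MeanRegressor,
    evaluate,
    evaluate_by_speed,
    fit_lasso,
    loso_cv,
    mean_regressor,
    split_subjects,
)


def lasso_objective(X, y, b0, beta, lam):
    """The penalized least-squares objective the fit must minimize."""
    n = len(y)
    resid = y - b0 - X @ beta
    return float(resid @ resid) / (2 * n) + lam * float(np.sum(np.abs(beta)))


def brute_force_lasso(X, y, lam, half_width=2.0, npts=21, rounds=6, shrink=0.2):
    """Multi-resolution grid minimization of the Lasso objective.

    The intercept is profiled out exactly (b0 = mean(y - X beta)); the
    coefficient vector is searched on a full grid refined around the best
    point.  Independent of any gradient/coordinate-descent solver.
    """
    k = X.shape[1]
    center = np.zeros(k)
    hw = half_width
    best = None
    for _ in range(rounds):
        axes = [np.linspace(c - hw, c + hw, npts) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        candidates = np.stack([g.ravel() for g in grids], axis=1)
        scores = []
        for beta in candidates:
            b0 = float(np.mean(y - X @ beta))
            scores.append(lasso_objective(X, y, b0, beta, lam))
        i = int(np.argmin(scores))
        center = candidates[i]
        best = (float(np.mean(y - X @ center)), center.copy(), scores[i])
        hw *= shrink
    return best


def standardized(rng, n, k):
    X = rng.normal(0, 1, (n, k))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return X


class TestFitLasso:
    def test_soft_threshold_closed_form(self, rng):
        """Single standardized feature: beta = sign(b_ols)*max(|b_ols|-lam, 0)."""
        n = 200
        x = standardized(rng, n, 1)[:, 0]
        y = 0.3 * x + rng.normal(0, 0.1, n)
        b_ols = float(x @ (y - y.mean())) / n
        for lam in (0.01, 0.1, 0.5):
            fit = fit_lasso(pd.DataFrame({"x": x}), y, lam)
            expected = np.sign(b_ols) * max(abs(b_ols) - lam, 0.0)
            assert fit.coefficients["x"] == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_agrees_with_brute_force_grid_oracle(self, k, rng):
        n = 20
        X = standardized(rng, n, k)
        beta_true = np.array([0.8, -0.5, 0.3])[:k]
        y = 1.5 + X @ beta_true + rng.normal(0, 0.1, n)
        lam = 0.05
        fit = fit_lasso(pd.DataFrame(X, columns=[f"f{i}" for i in range(k)]), y, lam)
        beta_fit = np.array([fit.coefficients[f"f{i}"] for i in range(k)])
        b0_bf, beta_bf, obj_bf = brute_force_lasso(X, y, lam)
        obj_fit = lasso_objective(X, y, fit.intercept, beta_fit, lam)
        assert obj_fit <= obj_bf + 1e-4
        assert np.allclose(beta_fit, beta_bf, atol=1e-3)

    def test_strong_penalty_reduces_to_mean(self, rng):
        n = 400
        X = standardized(rng, n, 5)
        y = rng.normal(3.0, 0.1, n)   # independent of the features
        fit = fit_lasso(pd.DataFrame(X, columns=list("abcde")), y, 0.05)
        assert all(c == 0.0 for c in fit.coefficients.values())
        assert fit.intercept == pytest.approx(np.mean(y), abs=1e-9)

    def test_zero_penalty_interpolates_two_points(self):
        X = pd.DataFrame({"x": [0.0, 1.0]})
        fit = fit_lasso(X, np.array([1.0, 3.0]), 0.0)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.coefficients["x"] == pytest.approx(2.0, abs=1e-9)

    def test_l1_norm_nonincreasing_along_grid(self, rng):
        n = 100
        X = standardized(rng, n, 6)
        beta = np.array([0.5, -0.4, 0.3, 0.0, 0.2, -0.1])
        y = X @ beta + rng.normal(0, 0.2, n)
        Xdf = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
        norms = [fit_lasso(Xdf, y, lam).l1_norm for lam in DEFAULT_LAMBDA_GRID]
        assert all(a >= b - 1e-9 for a, b in zip(norms[:-1], norms[1:]))

    def test_parameter_recovery_at_small_lambda(self, rng):
        """With a linear truth and weak regularization, the coefficients are
        recovered within 10% and test RMSE approaches the noise SD."""
        n, sigma = 2000, 0.05
        X = standardized(rng, n, 3)
        beta = np.array([0.8, -0.6, 0.4])
        y = 2.0 + X @ beta + rng.normal(0, sigma, n)
        fit = fit_lasso(pd.DataFrame(X, columns=list("abc")), y, 5e-6)
        got = np.array([fit.coefficients[c] for c in "abc"])
        assert np.all(np.abs(got - beta) / np.abs(beta) < 0.10)
        Xt = standardized(np.random.default_rng(99), 500, 3)
        yt = 2.0 + Xt @ beta + np.random.default_rng(98).normal(0, sigma, 500)
        pred = fit.predict(pd.DataFrame(Xt, columns=list("abc")))
        assert evaluate(pred, yt)["rmse"] == pytest.approx(sigma, rel=0.15)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_lasso(pd.DataFrame({"x": [1.0]}), np.array([1.0]), 0.01)


class TestSplitSubjects:
    def test_default_fraction_gives_36_7(self):
        ids = [f"S{i}" for i in range(43)]
        train, test = split_subjects(ids, seed=0)
        assert len(train) == 36 and len(test) == 7

    def test_disjoint_and_exhaustive(self):
        ids = [f"S{i}" for i in range(20)]
        train, test = split_subjects(ids, seed=3)
        assert set(train) | set(test) == set(ids)
        assert set(train) & set(test) == set()

    def test_seeded_determinism(self):
        ids = [f"S{i}" for i in range(20)]
        assert split_subjects(ids, seed=5) == split_subjects(ids, seed=5)
        assert split_subjects(ids, seed=5) != split_subjects(ids, seed=6)


class TestLosoCv:
    @staticmethod
    def _table(rng, n_subjects=4, steps=30):
        rows = []
        for s in range(n_subjects):
            x = rng.normal(0, 1, steps)
            z = rng.normal(0, 1, steps)
            y = 1.0 + 0.5 * x + rng.normal(0, 0.05, steps)
            for xi, zi, yi in zip(x, z, y):
                rows.append({"subject_id": f"S{s}", "x": xi, "z": zi, "y": yi})
        return pd.DataFrame(rows)

    def test_fold_count_equals_subject_count(self, rng):
        table = self._table(rng, n_subjects=5)
        res = loso_cv(table, "y", (1e-4, 1e-3, 1e-2))
        assert set(res.scores) == {1e-4, 1e-3, 1e-2}
        assert res.selected_lambda in res.scores

    def test_constant_target_gives_zero_rmse_everywhere(self, rng):
        table = self._table(rng)
        table["y"] = 3.14
        res = loso_cv(table, "y", (1e-4, 1e-2))
        assert all(s == pytest.approx(0.0, abs=1e-9) for s in res.scores.values())

    def test_informative_model_beats_mean_regressor(self, rng):
        table = self._table(rng, n_subjects=6)
        res = loso_cv(table, "y", DEFAULT_LAMBDA_GRID)
        # mean-regressor LOSO validation RMSE
        mean_scores = []
        for held in table["subject_id"].unique():
            tr = table[table["subject_id"] != held]
            va = table[table["subject_id"] == held]
            mr = MeanRegressor.fit(tr["y"].to_numpy())
            mean_scores.append(
                evaluate(mr.predict(va), va["y"].to_numpy())["rmse"]
            )
        assert res.validation["rmse"] < np.mean(mean_scores)

    def test_fold_fit_excludes_held_out_subject(self, rng):
        """With two subjects, each fold's score must equal an independent
        fit on the other subject alone (no held-out leakage, and the
        warm-started path matches fit_lasso)."""
        from vgrf.features import standardize

        table = self._table(rng, n_subjects=2, steps=40)
        lam = 0.01
        res = loso_cv(table, "y", (lam,))
        fold_rmses = []
        for held in sorted(table["subject_id"].unique()):
            tr = table[table["subject_id"] != held]
            va = table[table["subject_id"] == held]
            (tr_s, va_s), _ = standardize(
                tr.drop(columns=["y"]), va.drop(columns=["y"])
            )
            fit = fit_lasso(tr_s, tr["y"].to_numpy(), lam)
            fold_rmses.append(
                evaluate(fit.predict(va_s), va["y"].to_numpy())["rmse"]
            )
        assert res.scores[lam] == pytest.approx(np.mean(fold_rmses), abs=1e-9)


class TestMeanRegressor:
    def test_predicts_train_mean(self):
        mr = mean_regressor(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(mr.predict(np.empty(5)), 2.0)

    def test_single_value(self):
        assert mean_regressor(np.array([7.0])).mean == 7.0

    def test_negative_r2_on_shifted_test_set(self, rng):
        y_train = rng.normal(0, 1, 100)
        y_test = rng.normal(5, 1, 50)
        mr = mean_regressor(y_train)
        assert evaluate(mr.predict(y_test), y_test)["r2"] < 0


class TestMetrics:
    def test_perfect_predictions(self):
        m = evaluate(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        assert m["rmse"] == 0.0 and m["mape_percent"] == 0.0 and m["r2"] == 1.0

    def test_hand_computed_example(self):
        m = evaluate(np.array([1.0, 5.0]), np.array([2.0, 4.0]))
        assert m["mape_percent"] == pytest.approx(37.5)
        assert m["rmse"] == pytest.approx(1.0)

    def test_test_mean_predictor_has_zero_r2(self, rng):
        y = rng.normal(2, 1, 50)
        pred = np.full(50, y.mean())
        assert evaluate(pred, y)["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_speed_groups_mse_decomposition(self, rng):
        y = rng.normal(2.4, 0.3, 120)
        pred = y + rng.normal(0, 0.1, 120)
        speeds = rng.choice([2.22, 2.78, 3.33], 120)
        by = evaluate_by_speed(pred, y, speeds)
        total = sum(m["n_steps"] * m["rmse"] ** 2 for m in by.values())
        overall = evaluate(pred, y)
        assert total == pytest.approx(overall["n_steps"] * overall["rmse"] ** 2, rel=1e-9)

    def test_single_group_equals_overall(self, rng):
        y = rng.normal(2.4, 0.3, 60)
        pred = y + 0.1
        by = evaluate_by_speed(pred, y, np.full(60, 2.5))
        assert by[2.5] == evaluate(pred, y)

    def test_empty_group_omitted_with_warning(self, rng, caplog):
        import logging

        y = rng.normal(2.4, 0.3, 60)
        with caplog.at_level(logging.WARNING):
            by = evaluate_by_speed(y, y, np.full(60, 2.5), groups=[2.5, 9.9])
        assert 9.9 not in by and "9.9" in caplog.text
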