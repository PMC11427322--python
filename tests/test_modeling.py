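"""Unit tests for the lasso modeling chain."""

import math

import numpy as np
import pandas as pd
import pytest

from restoview.exceptions import ValidationError
from restoview.modeling import (
    LassoModelSpec,
    RestorativenessLasso,
    apply_model,
    compute_vif,
    cv_lasso,
    evaluate_rmse,
    fit_lasso,
    lambda_grid_from_data,
    published_models,
    split_train_test,
    sqrt_greenery_correlations,
    standardize,
    vif_prune,
)

from .reference import naive_vif_from_correlation


def random_design(n, p, seed=0, corr=0.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, p))
    if corr:
        shared = rng.normal(size=(n, 1))
        base = math.sqrt(1 - corr) * base + math.sqrt(corr) * shared
    return pd.DataFrame(base, columns=[f"x{j}" for j in range(p)])


class TestStandardize:
    def test_simple_column(self):
        Z, std = standardize(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert list(Z["a"]) == pytest.approx([-1.0, 0.0, 1.0])
        assert std.sds["a"] == pytest.approx(1.0)

    def test_idempotent(self):
        X = random_design(30, 3, seed=1)
        Z1, _ = standardize(X)
        Z2, _ = standardize(Z1)
        assert np.allclose(Z1, Z2, atol=1e-9)

    def test_columns_independent(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 30.0, 20.0]})
        Z, _ = standardize(X)
        for col in X:
            mu, sd = X[col].mean(), X[col].std(ddof=1)
            assert list(Z[col]) == pytest.approx(list((X[col] - mu) / sd))

    def test_zero_variance_names_column(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(ValidationError, match="flat"):
            standardize(X)

    def test_applied_to_new_data_reuses_parameters(self):
        X = random_design(20, 2, seed=2)
        _, std = standardize(X)
        fresh = random_design(5, 2, seed=3)
        Z = std.apply(fresh)
        assert np.allclose(Z, (fresh - X.mean()) / X.std(ddof=1))


class TestComputeVIF:
    def test_orthogonal_columns(self):
        raw = np.random.default_rng(3).normal(size=(12, 3))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered orthonormal columns
        vifs = compute_vif(pd.DataFrame(q, columns=list("abc")))
        assert np.allclose(vifs, 1.0, atol=1e-9)

    def test_perfect_collinearity_is_infinite(self):
        X = random_design(20, 2, seed=4)
        X["x2"] = X["x0"] + X["x1"]
        assert compute_vif(X)["x2"] == math.inf

    def test_matches_inverse_correlation_oracle(self):
        X = random_design(200, 3, seed=5, corr=0.81)
        Z, _ = standardize(X)
        ours = compute_vif(Z).to_numpy()
        oracle = naive_vif_from_correlation(Z.to_numpy())
        assert np.allclose(ours, oracle, atol=1e-6)


class TestVIFPrune:
    def test_orthogonal_nothing_removed(self):
        X = random_design(100, 4, seed=6)
        report = vif_prune(X, threshold=5.0)
        assert report.removal_trace == []
        assert report.retained == list(X.columns)

    def test_collinear_trio_pruned(self):
        rng = np.random.default_rng(7)
        X = random_design(60, 2, seed=7)
        X["x2"] = X["x0"] + X["x1"] + rng.normal(0, 0.01, 60)
        report = vif_prune(X, threshold=5.0)
        assert len(report.removal_trace) == 1
        final = compute_vif(X[report.retained])
        assert (final < 5.0).all()

    def test_protected_feature_never_removed(self):
        rng = np.random.default_rng(8)
        X = random_design(60, 2, seed=8)
        X["x2"] = X["x0"] + X["x1"] + rng.normal(0, 0.01, 60)
        report = vif_prune(X, threshold=5.0, protected={"x2"})
        assert "x2" in report.retained
        assert report.removal_trace[0][0] in ("x0", "x1")
        assert all(name != "x2" for name, _ in report.removal_trace)

    def test_terminates_and_satisfies_threshold(self):
        for seed in range(5):
            X = random_design(50, 8, seed=seed, corr=0.9)
            report = vif_prune(X, threshold=5.0)
            assert len(report.removal_trace) <= 8
            if len(report.retained) > 1:
                assert (compute_vif(X[report.retained]) < 5.0).all()


class TestSplit:
    def test_sixty_photos_fifty_ten(self):
        ids = [f"ph{i}" for i in range(60)]
        split = split_train_test(ids, n_test=10, seed=42)
        assert len(split.train_ids) == 50 and len(split.test_ids) == 10
        assert set(split.train_ids) | set(split.test_ids) == set(ids)
        assert not set(split.train_ids) & set(split.test_ids)

    def test_deterministic_per_seed(self):
        ids = list(range(30))
        assert split_train_test(ids, 5, seed=9) == split_train_test(ids, 5, seed=9)
        assert split_train_test(ids, 5, seed=9) != split_train_test(ids, 5, seed=10)

    def test_zero_test_boundary(self):
        split = split_train_test(list(range(10)), n_test=0, seed=0)
        assert len(split.train_ids) == 10 and split.test_ids == ()

    def test_too_large_test_rejected(self):
        with pytest.raises(ValidationError):
            split_train_test(list(range(10)), n_test=10, seed=0)


class TestFitLasso:
    def test_huge_penalty_shrinks_everything(self):
        X = random_design(40, 5, seed=10)
        y = np.arange(40, dtype=float)
        model = fit_lasso(X, y, lam=1e6)
        assert all(b == 0 for b in model.coefficients.values())
        assert model.intercept == pytest.approx(y.mean())

    def test_zero_penalty_matches_ols(self):
        X = random_design(50, 4, seed=11)
        rng = np.random.default_rng(11)
        y = X.to_numpy() @ np.array([1.0, -2.0, 0.5, 0.0]) + rng.normal(0, 0.1, 50)
        model = fit_lasso(X, y, lam=0.0)
        design = np.column_stack([np.ones(50), X.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-5)
        assert list(model.coefficients.values()) == pytest.approx(list(beta[1:]), abs=1e-5)

    def test_univariate_soft_threshold_closed_form(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=100)
        y = 1.5 * x + rng.normal(0, 0.3, 100)
        X = pd.DataFrame({"x": x})
        for lam in (0.05, 0.2, 0.8):
            model = fit_lasso(X, y, lam)
            xc = x - x.mean()
            yc = y - y.mean()
            rho = float(xc @ yc) / len(x)
            denom = float(xc @ xc) / len(x)
            expected = np.sign(rho) * max(abs(rho) - lam, 0.0) / denom
            assert model.coefficients["x"] == pytest.approx(expected, abs=1e-6)

    def test_kkt_conditions_on_random_instances(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = random_design(60, 6, seed=seed)
            y = X.to_numpy() @ rng.normal(size=6) + rng.normal(0, 0.5, 60)
            lam = 0.1
            model = fit_lasso(X, y, lam)
            beta = np.array(list(model.coefficients.values()))
            resid = y - model.intercept - X.to_numpy() @ beta
            grad = X.to_numpy().T @ resid / len(y)
            for g, b in zip(grad, beta):
                if b != 0:
                    assert g == pytest.approx(lam * np.sign(b), abs=1e-6)
                else:
                    assert abs(g) <= lam + 1e-6

    def test_coefficient_path_monotone_univariate(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=80)
        y = 2.0 * x + rng.normal(0, 0.2, 80)
        X = pd.DataFrame({"x": x})
        lams = np.geomspace(2.0, 1e-4, 30)
        betas = [fit_lasso(X, y, lam).coefficients["x"] for lam in lams]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(betas, betas[1:]))

    def test_non_finite_rejected(self):
        X = pd.DataFrame({"x": [1.0, np.nan, 2.0]})
        with pytest.raises(ValidationError):
            fit_lasso(X, [1.0, 2.0, 3.0], 0.1)


class TestCVLasso:
    def test_pure_noise_gives_intercept_only_at_1se(self):
        rng = np.random.default_rng(14)
        X = random_design(50, 6, seed=14)
        y = rng.normal(size=50)
        cv = cv_lasso(X, y, k=10, seed=14)
        model = fit_lasso(X, y, cv.lambda_1se)
        assert all(b == 0 for b in model.coefficients.values())

    def test_planted_signal_recovered_majority_of_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = random_design(50, 6, seed=100 + seed)
            y = 2.0 * X["x0"].to_numpy() + rng.normal(0, 0.3, 50)
            cv = cv_lasso(X, y, k=10, seed=seed)
            model = fit_lasso(X, y, cv.lambda_1se)
            if model.coefficients["x0"] > 0:
                hits += 1
        assert hits >= 15

    def test_one_se_rule_matches_exhaustive_scan(self):
        rng = np.random.default_rng(15)
        X = random_design(50, 5, seed=15)
        y = X["x1"].to_numpy() + rng.normal(0, 0.5, 50)
        cv = cv_lasso(X, y, k=10, seed=15)
        i_min = int(np.argmin(cv.mean_rmse))
        bound = cv.mean_rmse[i_min] + cv.se_rmse[i_min]
        best = max(
            (lam for lam, m in zip(cv.lambda_grid, cv.mean_rmse) if m <= bound)
        )
        assert cv.lambda_1se == best
        assert cv.lambda_1se >= cv.lambda_min
        assert cv.mean_rmse[list(cv.lambda_grid).index(cv.lambda_1se)] <= bound

    def test_fewer_rows_than_folds_rejected(self):
        X = random_design(5, 2, seed=16)
        with pytest.raises(ValidationError):
            cv_lasso(X, np.zeros(5), k=10, seed=0)

    def test_lambda_grid_spans_shrinkage(self):
        X = random_design(40, 3, seed=17)
        y = X["x0"].to_numpy()
        grid = lambda_grid_from_data(X, y)
        assert len(grid) == 100 and grid[0] > grid[-1] > 0
        top = fit_lasso(X, y, grid[0])
        assert all(b == 0 for b in top.coefficients.values())


class TestEvaluateRMSE:
    def test_hand_example(self):
        model = LassoModelSpec("y", intercept=0.0, coefficients={"x": 1.0})
        X = pd.DataFrame({"x": [1.0, 2.0]})
        assert evaluate_rmse(model, X, [2.0, 4.0]) == pytest.approx(math.sqrt(2.5))

    def test_perfect_predictions(self):
        model = LassoModelSpec("y", intercept=1.0, coefficients={"x": 2.0})
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        assert evaluate_rmse(model, X, [1.0, 3.0, 5.0]) == 0.0

    def test_intercept_only_on_constant_outcome(self):
        model = LassoModelSpec("y", intercept=2.928, coefficients={})
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        assert evaluate_rmse(model, X, [2.928] * 3) == 0.0

    def test_missing_column_rejected(self):
        model = LassoModelSpec("y", intercept=0.0, coefficients={"z": 1.0})
        with pytest.raises(ValidationError):
            evaluate_rmse(model, pd.DataFrame({"x": [1.0]}), [0.0])


class TestPublishedModels:
    def test_nonzero_coefficient_counts(self):
        models = published_models()
        counts = {k: len(m.nonzero_coefficients) for k, m in models.items()}
        assert counts == {"overall": 4, "being_away": 3, "fascination": 4, "extent": 0}

    def test_intercepts_at_standardized_origin(self):
        models = published_models()
        z0 = {name: 0.0 for name in models["overall"].coefficients}
        assert apply_model(models["overall"], z0) == 2.910
        assert apply_model(models["being_away"], {k: 0.0 for k in models["being_away"].coefficients}) == 2.972
        assert apply_model(models["fascination"], {k: 0.0 for k in models["fascination"].coefficients}) == 2.822

    def test_extent_is_intercept_only(self, rng):
        extent = published_models()["extent"]
        for _ in range(5):
            z = {"anything": rng.normal()}
            assert apply_model(extent, z) == 2.928

    def test_color_fractal_negative_everywhere_present(self):
        models = published_models()
        for name in ("overall", "being_away", "fascination"):
            assert models[name].coefficients["color_fractal"] < 0

    def test_being_away_at_unit_greenery_z(self):
        m = published_models()["being_away"]
        z = {k: 0.0 for k in m.coefficients}
        z["sqrt_greenery"] = 1.0
        assert apply_model(m, z) == pytest.approx(3.086)

    def test_overall_monotonicity(self, rng):
        m = published_models()["overall"]
        z = {k: float(rng.normal()) for k in m.coefficients}
        up = dict(z, sqrt_greenery=z["sqrt_greenery"] + 1.0)
        down = dict(z, color_fractal=z["color_fractal"] + 1.0)
        assert apply_model(m, up) > apply_model(m, z)
        assert apply_model(m, down) < apply_model(m, z)

    def test_missing_feature_rejected(self):
        m = published_models()["overall"]
        with pytest.raises(ValidationError):
            apply_model(m, {"sqrt_greenery": 0.0})


class TestSqrtGreeneryCorrelations:
    def _features(self, g_pct):
        return pd.DataFrame(
            {"sqrt_greenery": np.sqrt(g_pct)},
            index=[f"ph{i}" for i in range(len(g_pct))],
        )

    def _scores(self, overall):
        n = len(overall)
        return pd.DataFrame(
            {
                "photo_id": [f"ph{i}" for i in range(n)],
                "overall_mean": overall,
                "being_away_mean": overall,
                "fascination_mean": overall,
                "extent_mean": np.random.default_rng(0).normal(3, 0.1, n),
            }
        )

    def test_exact_linear_relation_gives_unit_correlation(self):
        g = np.linspace(0, 60, 20)
        feats = self._features(g)
        scores = self._scores(2.5 + 0.15 * np.sqrt(g))
        table = sqrt_greenery_correlations(feats, scores)
        assert table.loc["overall", "r_sqrt_greenery"] == pytest.approx(1.0)
        assert table.loc["being_away", "r_sqrt_greenery"] == pytest.approx(1.0)

    def test_independent_scores_give_small_correlation(self):
        rng = np.random.default_rng(21)
        rs = []
        for _ in range(100):
            g = np.linspace(0, 60, 60)
            feats = self._features(g)
            scores = self._scores(rng.normal(3, 0.3, 60))
            rs.append(sqrt_greenery_correlations(feats, scores).loc["overall", "r_sqrt_greenery"])
        assert np.mean(np.abs(rs)) < 0.2

    def test_planted_correlation_recovered(self):
        # r = b sd(sqrt g) / sqrt(b^2 var(sqrt g) + sigma^2), solved for sigma
        rng = np.random.default_rng(22)
        g = np.linspace(0, 60, 60)
        sg = np.sqrt(g)
        b, target_r = 0.15, 0.68
        sigma = b * sg.std() * math.sqrt(1 / target_r**2 - 1)
        rs = []
        for _ in range(50):
            scores = self._scores(2.5 + b * sg + rng.normal(0, sigma, 60))
            rs.append(sqrt_greenery_correlations(self._features(g), scores).loc["overall", "r_sqrt_greenery"])
        assert np.mean(rs) == pytest.approx(target_r, abs=0.1)

    def test_too_few_photos_rejected(self):
        with pytest.raises(ValidationError):
            sqrt_greenery_correlations(self._features([1.0, 2.0]), self._scores([3.0, 3.1]))


class TestModelResultsRoundTrip:
    def test_json_round_trip(self, tmp_path):
        Z, std = standardize(random_design(30, 3, seed=23))
        model = LassoModelSpec(
            "overall", 2.9, {"x0": 0.1, "x1": 0.0, "x2": -0.2}, lam=0.05, standardization=std
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = LassoModelSpec.from_json(path)
        assert back.coefficients == model.coefficients
        assert back.intercept == model.intercept
        assert back.lam == model.lam
        assert np.allclose(back.standardization.means, model.standardization.means)


class TestRestorativenessLasso:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(24)
        n = 60
        X = pd.DataFrame(
            rng.normal(size=(n, 6)),
            columns=["sqrt_greenery", "color_fractal", "a", "b", "c", "d"],
            index=[f"ph{i:02d}" for i in range(n)],
        )
        y = 3.0 + 0.4 * X["sqrt_greenery"] - 0.3 * X["color_fractal"] + rng.normal(0, 0.1, n)
        scores = pd.DataFrame({"photo_id": X.index, "overall_mean": y.to_numpy()})
        return X, scores

    def test_fit_selects_planted_terms_with_signs(self, planted):
        X, scores = planted
        res = RestorativenessLasso(X, scores, outcome="overall").fit(seed=7)
        nz = res.model_spec.nonzero_coefficients
        assert nz["sqrt_greenery"] > 0
        assert nz["color_fractal"] < 0

    def test_no_overfit_on_planted_data(self, planted):
        X, scores = planted
        res = RestorativenessLasso(X, scores).fit(seed=7)
        assert res.rmse_test < 2 * res.rmse_train + 0.05

    def test_summary_mentions_key_quantities(self, planted):
        X, scores = planted
        res = RestorativenessLasso(X, scores).fit(seed=7)
        text = res.summary()
        assert "lambda_1se" in text and "RMSE" in text and "sqrt_greenery" in text

    def test_predictions_align_with_manual_application(self, planted):
        X, scores = planted
        res = RestorativenessLasso(X, scores).fit(seed=7)
        pred = res.predict(X)
        z = res.model_spec.standardization.apply(X).iloc[0]
        manual = apply_model(res.model_spec, z.to_dict())
        assert pred.iloc[0] == pytest.approx(manual)

    def test_unmatched_photo_ids_rejected(self, planted):
        X, scores = planted
        with pytest.raises(ValidationError):
            RestorativenessLasso(X.iloc[:-1], scores)
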