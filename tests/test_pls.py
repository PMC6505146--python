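"""NIPALS PLS1: decomposition identities, cross-validated component choice,
prediction consistency and coefficient ranking."""

import numpy as np
import pandas as pd
import pytest

from ricegxe.pls import (build_pls_design, fit_nipals, pls_predict,
                         rank_covariates, select_components)


class TestFit:
    def test_single_component_equals_ols_on_one_predictor(self, rng):
        x = rng.normal(size=40)
        y = 2.0 * x + rng.normal(0, 0.3, 40)
        m = fit_nipals(x[:, None], y, 1)
        xs = (x - x.mean()) / x.std(ddof=1)
        slope = float(xs @ (y - y.mean()) / (xs @ xs))
        assert m.coefficients.iloc[0] == pytest.approx(slope, rel=1e-10)

    def test_exact_fit_at_full_rank(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + 1.0
        m = fit_nipals(X, y, 5)
        assert np.linalg.norm(m.residual_y) < 1e-6

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(40, 12))
        y = rng.normal(size=40)
        m = fit_nipals(X, y, 6)
        TtT = m.scores.T @ m.scores
        off = TtT - np.diag(np.diag(TtT))
        assert np.abs(off).max() < 1e-8

    def test_training_error_monotone_in_components(self, rng):
        X = rng.normal(size=(50, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 1, 50)
        m = fit_nipals(X, y, 8)
        Xs = (X - m.predictor_center) / m.predictor_scale
        errs = [np.mean((m.response_center + Xs @ m.coef_path[:, c] - y) ** 2)
                for c in range(m.n_components)]
        assert all(errs[i + 1] <= errs[i] + 1e-12 for i in range(len(errs) - 1))

    def test_coefficients_reproduce_score_predictions(self, rng):
        X = rng.normal(size=(35, 9))
        y = rng.normal(size=35)
        m = fit_nipals(X, y, 4)
        via_scores = m.response_center + m.scores @ m.y_loadings
        via_coefs = pls_predict(m, X)
        assert np.allclose(via_scores, via_coefs, atol=1e-8)

    def test_rank_exhaustion_truncates_with_warning(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -1.0, 0.5])
        with pytest.warns(UserWarning, match="truncat"):
            m = fit_nipals(X, y, 10)
        assert m.n_components <= 3

    def test_zero_variance_predictor_rejected(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        with pytest.raises(ValueError):
            fit_nipals(X, rng.normal(size=20), 1)


class TestSelect:
    def test_same_seed_same_curve(self, rng):
        X = rng.normal(size=(60, 20))
        y = rng.normal(size=60)
        c1 = select_components(X, y, max_lv=5, seed=7)
        c2 = select_components(X, y, max_lv=5, seed=7)
        assert c1.chosen_c == c2.chosen_c
        assert np.allclose(c1.rmsep, c2.rmsep)

    def test_two_latent_factors_recovered(self):
        rng = np.random.default_rng(42)
        n, p = 200, 100
        F = rng.normal(size=(n, 2))
        L = rng.normal(size=(2, p))
        X = F @ L + 0.3 * rng.normal(size=(n, p))
        y = F @ np.array([2.0, -1.5]) + 0.3 * rng.normal(size=n)
        curve = select_components(X, y, max_lv=8, seed=0)
        assert curve.chosen_c in (2, 3)

    def test_pure_noise_gains_nothing(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(120, 30))
        y = rng.normal(size=120)
        curve = select_components(X, y, max_lv=8, seed=0)
        assert curve.rmsep.iloc[0] <= 1.10 * curve.rmsep.min()

    def test_invalid_max_lv(self, rng):
        with pytest.raises(ValueError):
            select_components(rng.normal(size=(30, 5)), rng.normal(size=30),
                              max_lv=0)


class TestPredict:
    def test_training_row_reproduces_fitted_value(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        m = fit_nipals(X, y, 3)
        fitted = pls_predict(m, X)
        assert pls_predict(m, X[3:4])[0] == pytest.approx(fitted[3])

    def test_predictor_means_give_response_mean(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        m = fit_nipals(X, y, 3)
        assert pls_predict(m, X.mean(axis=0)[None, :])[0] == pytest.approx(
            y.mean(), abs=1e-10)

    def test_missing_column_named(self, rng):
        X = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        m = fit_nipals(X, rng.normal(size=25), 2)
        with pytest.raises(ValueError, match="b"):
            pls_predict(m, X.drop(columns="b"))


class TestRanking:
    def test_planted_signal_ranks_first_with_sign(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 5)),
                         columns=[f"v{j}" for j in range(5)])
        y = 2.0 * (X["v1"] - X["v1"].mean()) / X["v1"].std(ddof=1)
        m = fit_nipals(X, y.to_numpy(), 2)
        tab = rank_covariates(m)
        assert tab.iloc[0]["name"] == "v1"
        assert tab.iloc[0]["coefficient"] > 0

    def test_duplicated_predictor_shares_coefficient(self, rng):
        x = rng.normal(size=60)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=60)})
        y = x + rng.normal(0, 0.2, 60)
        m = fit_nipals(X, y, 2)
        assert m.coefficients["a"] == pytest.approx(m.coefficients["b"], rel=1e-8)
        tab = rank_covariates(m, subset=["a", "b"])
        assert list(tab["name"]) == ["a", "b"]  # tie broken by name

    def test_top_five_report(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 8)),
                         columns=[f"EC{j}_M" for j in range(8)])
        m = fit_nipals(X, rng.normal(size=40), 2)
        tab = rank_covariates(m, subset="_M$").head(5)
        assert len(tab) == 5

    def test_empty_subset_rejected(self, rng):
        m = fit_nipals(pd.DataFrame(rng.normal(size=(20, 3)),
                                    columns=list("xyz")),
                       rng.normal(size=20), 1)
        with pytest.raises(ValueError):
            rank_covariates(m, subset=["missing"])


class TestDesign:
    def test_gw_design_appends_year_ec(self, unbalanced_dataset):
        ds = unbalanced_dataset
        blues = ds.trial.rename(columns={"trait": "value"})[
            ["year", "genotype", "value"]]
        Xg, y, _ = build_pls_design(blues, ds.genotypes.dosage)
        Xgw, y2, _ = build_pls_design(blues, ds.genotypes.dosage, ds.ec_raw)
        assert Xgw.shape[1] == Xg.shape[1] + ds.ec_raw.shape[1]
        assert np.allclose(y, y2)
        # EC columns are constant within a year
        first_year = blues["year"].iloc[0]
        sub = Xgw.loc[(blues["year"] == first_year).to_numpy(), ds.ec_raw.columns]
        assert (sub.nunique() == 1).all()
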