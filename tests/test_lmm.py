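"""REML engine, trial analyses, kernel constructors and BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricegxe import lmm
from ricegxe.lmm import (RandomTerm, bh_fdr, env_relationship, estimate_blues,
                         genomic_relationship, heritability, incidence,
                         interaction_kernel, reml_fit, variance_partition)
from ricegxe.synthetic import SimConfig, simulate_dataset


class TestREML:
    def test_balanced_one_way_matches_anova(self, rng):
        # balanced random-groups design: REML equals the ANOVA estimator
        g, r = 12, 6
        groups = np.repeat(np.arange(g), r)
        y = rng.normal(0, 1.3, g)[groups] + rng.normal(0, 0.8, g * r)
        Z, _ = incidence(groups)
        fit = reml_fit(y, np.ones((g * r, 1)), [RandomTerm("group", Z=Z)])
        means = np.array([y[groups == i].mean() for i in range(g)])
        msb = r * np.var(means, ddof=1)
        msw = sum(np.var(y[groups == i], ddof=1) for i in range(g)) / g * (r - 1) / (r - 1)
        msw = np.mean([np.sum((y[groups == i] - means[i]) ** 2) for i in range(g)]) / (r - 1)
        assert fit.variance_components["group"] == pytest.approx(
            max((msb - msw) / r, 0.0), rel=1e-4, abs=1e-6)
        assert fit.variance_components["Residual"] == pytest.approx(msw, rel=1e-4)

    def test_constant_response_all_zero(self):
        y = np.full(20, 3.5)
        Z, _ = incidence(np.arange(20) % 4)
        fit = reml_fit(y, np.ones((20, 1)), [RandomTerm("g", Z=Z)])
        assert all(v == pytest.approx(0.0, abs=1e-10)
                   for v in fit.variance_components.values())

    def test_matches_brute_force_optimizer(self, rng):
        # independent direct maximization of the restricted likelihood
        from scipy import optimize

        def brute(y, X, covs):
            n, p = X.shape

            def negll(logs):
                V = sum(np.exp(s) * C for s, C in zip(logs, covs))
                V = V + np.exp(logs[-1]) * np.eye(n)
                sign, ldV = np.linalg.slogdet(V)
                if sign <= 0:
                    return np.inf
                Vi = np.linalg.inv(V)
                XtViX = X.T @ Vi @ X
                s2, ldX = np.linalg.slogdet(XtViX)
                beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
                res = y - X @ beta
                return 0.5 * (ldV + ldX + res @ Vi @ res + (n - p) * np.log(2 * np.pi))

            best = None
            for _ in range(4):
                x0 = rng.normal(np.log(np.var(y) / (len(covs) + 1)), 1.0,
                                size=len(covs) + 1)
                r = optimize.minimize(negll, x0, method="Nelder-Mead",
                                      options={"maxiter": 3000, "xatol": 1e-10,
                                               "fatol": 1e-12})
                if best is None or r.fun < best.fun:
                    best = r
            return np.exp(best.x), -best.fun

        for _ in range(8):
            n, q1, q2 = 40, 5, 7
            Z1, _ = incidence(rng.integers(0, q1, n))
            Z2, _ = incidence(rng.integers(0, q2, n))
            q1, q2 = Z1.shape[1], Z2.shape[1]
            A = rng.normal(size=(q2, q2))
            K2 = A @ A.T / q2
            y = (Z1 @ rng.normal(0, 1, q1)
                 + Z2 @ (np.linalg.cholesky(K2 + 1e-8 * np.eye(q2)) @ rng.normal(0, 1, q2))
                 + rng.normal(0, 1, n))
            X = np.column_stack([np.ones(n), rng.normal(size=n)])
            fit = reml_fit(y, X, [RandomTerm("a", Z=Z1), RandomTerm("b", Z=Z2, K=K2)])
            s_bf, ll_bf = brute(y, X, [Z1 @ Z1.T, Z2 @ K2 @ Z2.T])
            assert fit.log_likelihood == pytest.approx(ll_bf, abs=1e-3)
            assert np.allclose(list(fit.variance_components.values()), s_bf, atol=1e-3)

    def test_non_psd_kernel_rejected(self, rng):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        Z, _ = incidence([0, 1, 0, 1])
        with pytest.raises(ValueError, match="positive semidefinite"):
            reml_fit(rng.normal(size=4), np.ones((4, 1)), [RandomTerm("k", Z=Z, K=K)])

    def test_likelihood_reported_at_estimates(self, rng):
        n = 30
        Z, _ = incidence(rng.integers(0, 5, n))
        y = rng.normal(size=n)
        fit = reml_fit(y, np.ones((n, 1)), [RandomTerm("g", Z=Z)])
        assert fit.converged
        assert np.isfinite(fit.log_likelihood)


class TestBLUEs:
    def test_single_observation_is_its_own_blue(self):
        df = pd.DataFrame({"year": 1, "genotype": list("abc"), "block": "B1",
                           "row": [1, 2, 3], "col": 1, "trait": [1.0, 2.0, 7.0]})
        bs = estimate_blues(df, "trait")
        assert np.allclose(bs.blues.sort_index().to_numpy(), [1.0, 2.0, 7.0])

    def test_reduces_to_means_without_design_variance(self):
        df = pd.DataFrame({"year": 1, "genotype": list("aabbcc"),
                           "block": "B1", "row": 1, "col": 1,
                           "trait": [1.0, 2.0, 3.0, 5.0, 4.0, 6.0]})
        bs = estimate_blues(df, "trait")
        assert np.allclose(bs.blues.sort_index().to_numpy(), [1.5, 4.0, 5.0])

    def test_blues_beat_raw_means_under_block_effects(self, rng):
        # unbalanced incomplete blocks with dominant block variance
        n_lines, n_blocks = 40, 8
        truth = rng.normal(0, 1, n_lines)
        block_eff = rng.normal(0, 4, n_blocks)
        rows = []
        for b in range(n_blocks):
            present = rng.choice(n_lines, size=20, replace=False)
            for g in present:
                rows.append({"year": 1, "genotype": f"g{g:02d}", "block": f"B{b}",
                             "row": 1, "col": 1,
                             "trait": truth[g] + block_eff[b] + rng.normal(0, 0.5)})
        df = pd.DataFrame(rows)
        bs = estimate_blues(df, "trait")
        raw = df.groupby("genotype")["trait"].mean()
        t = pd.Series(truth, index=[f"g{g:02d}" for g in range(n_lines)])
        r_blue = np.corrcoef(bs.blues.sort_index(), t.loc[bs.blues.sort_index().index])[0, 1]
        r_raw = np.corrcoef(raw.sort_index(), t.loc[raw.sort_index().index])[0, 1]
        assert r_blue > r_raw

    def test_missing_genotype_warned(self):
        df = pd.DataFrame({"year": 1, "genotype": list("aab"), "block": "B1",
                           "row": 1, "col": 1, "trait": [1.0, 2.0, np.nan]})
        with pytest.warns(UserWarning, match="without records"):
            bs = estimate_blues(df, "trait")
        assert list(bs.blues.index) == ["a"]


class TestHeritability:
    @pytest.mark.parametrize("sg,se,r,expected", [
        (1.0, 0.0, 1, 1.0),
        (1.0, 1.0, 2, 2.0 / 3.0),
        (1.0, 1.0, 1, 0.5),
    ])
    def test_line_mean_formula(self, sg, se, r, expected):
        assert heritability(sg, se, r) == pytest.approx(expected)

    def test_undefined_when_no_variance(self):
        with pytest.raises(ValueError):
            heritability(0.0, 0.0, 2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(sg=st.floats(0.0, 10.0), se=st.floats(0.0, 10.0),
           r=st.integers(1, 5))
    def test_bounded_in_unit_interval(self, sg, se, r):
        if sg == 0 and se == 0:
            return
        assert 0.0 <= heritability(sg, se, r) <= 1.0


class TestVariancePartition:
    def test_percents_sum_to_100(self, small_dataset):
        vp = variance_partition(small_dataset.trial, "trait")
        assert vp.table["percent"].sum() == pytest.approx(100.0, abs=0.1)
        assert list(vp.table["component"]) == lmm.VARPART_COMPONENTS

    def test_null_interaction_estimated_near_zero(self):
        targets = {"Year": 0.45, "Genotype": 0.2, "GxY": 0.0, "Column": 0.0,
                   "Row": 0.0, "Block": 0.1, "Residual": 0.25}
        cfg = SimConfig(n_lines=100, n_markers=60, n_years=3, replicates=2,
                        drop_fraction=0.0, n_rows=10, n_cols=10,
                        variance_targets=targets, seed=31)
        ds = simulate_dataset(cfg)
        vp = variance_partition(ds.trial, "trait")
        assert vp.percent("GxY") < 3.0

    def test_single_year_rejected(self, small_dataset):
        one = small_dataset.trial[small_dataset.trial["year"]
                                  == small_dataset.config.years[0]]
        with pytest.raises(ValueError):
            variance_partition(one, "trait")


class TestKernels:
    def test_genomic_relationship_hand_case(self):
        X = np.array([[1.0, -1.0], [-1.0, 0.0], [0.0, 1.0]])
        G = genomic_relationship(X)
        assert np.allclose(G, X @ X.T / 2)
        assert np.allclose(G, G.T)

    def test_duplicate_lines_share_entries(self, rng):
        X = rng.normal(size=(4, 6))
        X[1] = X[0]
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        G = genomic_relationship(X)
        assert G[0, 0] == pytest.approx(G[1, 1])
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_zero_matrix(self):
        assert np.allclose(genomic_relationship(np.zeros((3, 1)) + [[1], [1], [1]]
                                                - 1), 0.0)

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            genomic_relationship(X)

    def test_env_relationship_rank_one(self):
        w = np.array([[1.0], [-0.5], [-0.5]])
        Om = env_relationship(w)
        assert np.allclose(Om, np.outer(w, w))

    def test_interaction_kernel_identities(self, rng):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.allclose(interaction_kernel(A, np.ones((2, 2))), A)
        assert np.allclose(interaction_kernel(A, np.eye(2)), np.diag([1.0, 1.0]))
        B = rng.normal(size=(5, 5))
        B = B @ B.T
        C = rng.normal(size=(5, 5))
        C = C @ C.T
        eig = np.linalg.eigvalsh(interaction_kernel(B, C))
        assert eig.min() >= -1e-8 * max(eig.max(), 1.0)
        with pytest.raises(ValueError):
            interaction_kernel(A, np.ones((3, 3)))


class TestBHFDR:
    def test_hand_step_up(self):
        flags = bh_fdr(np.array([0.01, 0.02, 0.04, 0.5]), alpha=0.05)
        assert flags.tolist() == [True, True, False, False]

    def test_all_ones_none_rejected(self):
        assert not bh_fdr(np.ones(5)).any()

    def test_single_pvalue_plain_threshold(self):
        assert bh_fdr(np.array([0.04]), alpha=0.05).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_rejections_monotone_in_p(self, pvals):
        p = np.asarray(pvals)
        flags = bh_fdr(p)
        if flags.any():
            assert flags[p <= p[flags].max()].all()
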