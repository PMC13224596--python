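"""Batch normalization, mixed-model adjustment and reduced-rank regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from dietkidney.rrr_engine import (
    MEDIATORS,
    adjust_mediators,
    fit_random_intercept,
    fit_rrr,
    quantile_normalize_batches,
    reml_criterion,
    score_subjects,
    select_rank,
)


class TestQuantileNormalize:
    def test_single_batch_identity(self):
        x = np.array([3.0, 1, 4, 1, 5])
        out = quantile_normalize_batches(x, np.array(["A"] * 5))
        np.testing.assert_array_equal(out, x)

    def test_constant_shift_maps_to_reference_order_stats(self):
        ref = np.array([1.0, 2.0, 3.5, 7.0, 9.0])
        shifted = ref + 100.0
        x = np.r_[shifted, ref]
        b = np.array(["A"] * 5 + ["B"] * 5)  # B sorts last -> reference
        out = quantile_normalize_batches(x, b)
        # hand mapping: value at rank i in A -> reference sorted value i
        np.testing.assert_allclose(np.sort(out[:5]), np.sort(ref), atol=1e-12)
        np.testing.assert_array_equal(out[5:], ref)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(2, 1, 40), rng.normal(0, 1, 60)]
        b = np.array(["A"] * 40 + ["B"] * 60)
        out = quantile_normalize_batches(x, b)
        from scipy.stats import spearmanr
        assert spearmanr(x[:40], out[:40]).statistic == pytest.approx(1.0)

    def test_empty_reference_error(self):
        with pytest.raises(ValueError, match="reference"):
            quantile_normalize_batches(np.ones(3), np.array(["A"] * 3),
                                       reference="Z")


class TestRandomIntercept:
    def _balanced(self, a=25, m=4, su=1.0, se=0.7, seed=4):
        rng = np.random.default_rng(seed)
        u = rng.normal(0, su, a)
        y = 3.0 + np.repeat(u, m) + rng.normal(0, se, a * m)
        hh = np.repeat(np.arange(a), m)
        return y, np.ones((a * m, 1)), hh

    def test_balanced_anova_closed_form(self):
        y, X, hh = self._balanced()
        fit = fit_random_intercept(y, X, hh)
        a, m = 25, 4
        ybar_g = y.reshape(a, m).mean(1)
        msb = m * np.sum((ybar_g - y.mean()) ** 2) / (a - 1)
        msw = np.sum((y.reshape(a, m) - ybar_g[:, None]) ** 2) / (a * (m - 1))
        assert fit.sigma_e2 == pytest.approx(msw, abs=1e-4)
        assert fit.sigma_u2 == pytest.approx((msb - msw) / m, abs=1e-4)

    def test_tiny_data_grid_search_oracle(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=9) + np.repeat(rng.normal(0, 1.2, 3), 3)
        hh = np.repeat(np.arange(3), 3)
        X = np.ones((9, 1))
        fit = fit_random_intercept(y, X, hh)
        uniq, inv = np.unique(hh, return_inverse=True)
        sizes = np.bincount(inv).astype(float)
        thetas = np.exp(np.linspace(-14, 9, 40001))
        crits = [reml_criterion(t, y, X, inv, sizes)[0] for t in thetas]
        grid_min = min(min(crits), reml_criterion(0.0, y, X, inv, sizes)[0])
        assert fit.criterion == pytest.approx(grid_min, abs=1e-6)

    def test_statsmodels_mixedlm_cross_check(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(12)
        a, m = 40, 3
        age = rng.uniform(20, 70, a * m)
        y = 5 + 0.2 * age + np.repeat(rng.normal(0, 1.1, a), m) \
            + rng.normal(0, 0.9, a * m)
        hh = np.repeat(np.arange(a), m)
        fit = fit_random_intercept(y, np.column_stack([np.ones(a * m), age]), hh)
        df = pd.DataFrame({"y": y, "age": age, "g": hh})
        mm = sm.MixedLM.from_formula("y ~ age", groups="g", data=df).fit(reml=True)
        assert fit.beta[1] == pytest.approx(mm.params["age"], abs=1e-4)
        assert fit.sigma_u2 == pytest.approx(float(mm.cov_re.iloc[0, 0]), abs=1e-3)
        assert fit.sigma_e2 == pytest.approx(mm.scale, abs=1e-3)

    def test_zero_household_variance_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        n = 120
        age = rng.uniform(20, 70, n)
        y = 2 + 0.1 * age + rng.normal(0, 1, n)  # no household effect
        hh = np.arange(n) % 40
        X = np.column_stack([np.ones(n), age])
        panel = pd.DataFrame({"m": y})
        adj = adjust_mediators(panel, age, hh)
        ols_resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        # sigma_u ~ 0 -> mixed-model residuals ~ OLS residuals
        np.testing.assert_allclose(adj["m"], ols_resid, atol=2e-2)
        assert abs(np.corrcoef(adj["m"], age)[0, 1]) < 1e-6

    def test_adjusted_exactly_orthogonal_to_age(self):
        rng = np.random.default_rng(6)
        n = 200
        age = rng.uniform(20, 70, n)
        hh = rng.integers(0, 60, n)
        panel = pd.DataFrame({"m": 1 + 0.3 * age
                              + rng.normal(0, 1, 60)[hh] + rng.normal(0, 1, n)})
        adj = adjust_mediators(panel, age, hh)
        assert abs(np.corrcoef(adj["m"], age)[0, 1]) < 1e-10

    def test_single_household_error(self):
        with pytest.raises(ValueError, match="household"):
            fit_random_intercept(np.ones(5), np.ones((5, 1)), np.zeros(5))


def _standardize(M):
    return (M - M.mean(0)) / M.std(0, ddof=1)


class TestFitRRR:
    def test_noiseless_single_direction(self):
        rng = np.random.default_rng(1)
        n, p = 200, 5
        X = rng.normal(size=(n, p))
        w = np.array([1.0, -2.0, 0.5, 0.0, 1.5])
        Y = (X @ w)[:, None]  # single noiseless response
        model = fit_rrr(X, Y, K=1)
        s = model.scores["dp1"].to_numpy()
        r = np.corrcoef(s, X @ w)[0, 1]
        assert abs(r) > 1 - 1e-10
        assert model.explained_variance_share == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal(self, derived):
        _, _, models, _ = derived
        for m in models.values():
            r = np.corrcoef(m.scores["dp1"], m.scores["dp2"])[0, 1]
            assert abs(r) < 1e-8

    def test_brute_force_first_component_oracle(self):
        # p=3, q=2, n=50: numeric maximization of explained response
        # variance over unit predictor weights
        rng = np.random.default_rng(7)
        n = 50
        X = rng.normal(size=(n, 3))
        Y = np.column_stack([
            X @ np.array([1.0, 0.5, -0.3]) + rng.normal(0, 0.5, n),
            X @ np.array([-0.2, 1.0, 0.8]) + rng.normal(0, 0.5, n),
        ])
        model = fit_rrr(X, Y, K=2)
        Xs, Ys = _standardize(X), _standardize(Y)

        def neg_explained(w):
            s = Xs @ w
            return -float((Ys.T @ s) @ (Ys.T @ s) / (s @ s))

        best = -np.inf
        for seed in range(10):
            w0 = np.random.default_rng(seed).normal(size=3)
            res = minimize(neg_explained, w0 / np.linalg.norm(w0),
                           method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-12,
                                    "maxiter": 5000})
            best = max(best, -res.fun)
        assert model.eigenvalues[0] == pytest.approx(best, rel=1e-6)

    def test_full_rank_share_equals_multivariate_ols_r2(self):
        rng = np.random.default_rng(9)
        n = 120
        X = rng.normal(size=(n, 4))
        Y = X @ rng.normal(size=(4, 2)) + rng.normal(0, 1, size=(n, 2))
        model = fit_rrr(X, Y, K=2)  # K = q
        Xs, Ys = _standardize(X), _standardize(Y)
        Yhat = Xs @ np.linalg.lstsq(Xs, Ys, rcond=None)[0]
        r2 = np.sum(Yhat ** 2) / np.sum(Ys ** 2)
        assert model.explained_variance_share == pytest.approx(r2, abs=1e-12)

    def test_explained_shares_nonincreasing_cumulative_le_one(self, derived):
        _, _, models, _ = derived
        for m in models.values():
            lam = m.eigenvalues
            assert np.all(np.diff(lam) <= 1e-9)
            assert 0 <= m.explained_variance_share <= 1

    def test_sign_convention(self, derived):
        _, _, models, _ = derived
        for m in models.values():
            for k in range(m.rank):
                a = m.predictor_weights[:, k]
                assert a[np.argmax(np.abs(a))] > 0

    def test_rank_deficient_error(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 3))
        X = np.column_stack([X, X[:, 0]])  # duplicated column
        Y = rng.normal(size=(50, 2))
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_rrr(X, Y, K=1)


class TestSelectRank:
    @pytest.mark.parametrize("eig,policy,expected", [
        ((10, 5, 0.1), "ratio", 2),       # direct threshold rule
        ((1, 1, 1, 1), "ratio", 2),       # all equal -> cap
        ((10, 0.5, 0.1), "ratio", 1),
        ((10, 5, 4, 3), "fixed", 2),      # fixed two-pattern mode
        ((7,), "ratio", 1),
    ])
    def test_policies(self, eig, policy, expected):
        assert select_rank(np.array(eig, float), policy) == expected


class TestScoreSubjects:
    def test_training_idempotence_and_centering(self, derived):
        diet, _, models, _ = derived
        m = models["male"]
        X = diet.group_intake_adjusted.loc[m.scores.index]
        again = score_subjects(m, X)
        np.testing.assert_allclose(again.to_numpy(), m.scores.to_numpy(),
                                   atol=1e-10)
        at_mean = pd.DataFrame([m.x_mean], columns=m.x_columns)
        np.testing.assert_allclose(score_subjects(m, at_mean).to_numpy(),
                                   0.0, atol=1e-10)

    def test_row_permutation_equivariance(self, derived):
        diet, _, models, _ = derived
        m = models["male"]
        X = diet.group_intake_adjusted.loc[m.scores.index]
        perm = X.sample(frac=1.0, random_state=0)
        out = score_subjects(m, perm)
        np.testing.assert_allclose(out.to_numpy(),
                                   m.scores.loc[perm.index].to_numpy(),
                                   atol=1e-10)

    def test_column_mismatch_error(self, derived):
        diet, _, models, _ = derived
        m = models["male"]
        X = diet.group_intake_adjusted.drop(columns=["group_01"])
        with pytest.raises(ValueError, match="group_01"):
            score_subjects(m, X)


def test_sex_specific_fits_independent(small_cohort):
    """Permuting the other sex's rows leaves a sex's model unchanged."""
    from dietkidney.pipeline import derive_scores, prepare_sample
    tables, _ = prepare_sample(small_cohort)
    _, _, models, _ = derive_scores(tables)
    shuffled = {k: v.copy() for k, v in tables.items()}
    cov = shuffled["covariates"]
    fem_ids = cov.loc[cov.sex == "female", "subject_id"].tolist()
    rng = np.random.default_rng(0)
    perm = rng.permutation(fem_ids)
    for name in ("ffq", "biomarkers", "creatinine"):
        t = shuffled[name].set_index("subject_id")
        t.loc[fem_ids] = t.loc[perm].to_numpy()
        shuffled[name] = t.reset_index()
    _, _, models2, _ = derive_scores(shuffled)
    np.testing.assert_allclose(models["male"].predictor_weights,
                               models2["male"].predictor_weights, atol=1e-10)
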