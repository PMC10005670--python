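"""Logistic/linear response models and supporting statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import expit

from trigrs.models import (
    ResponseModel,
    delta_r2,
    fit_logistic,
    group_ttest,
    mcfadden_r2,
    snp_visit_interaction,
)


def logit_design(n=60, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    p = expit(0.5 + 1.2 * x - 0.8 * z)
    y = rng.binomial(1, p)
    return y, pd.DataFrame({"x": x, "z": z})


class TestFitLogistic:
    def test_intercept_only_fits_prevalence(self):
        y = np.array([1, 1, 1, 0, 0])
        res = fit_logistic(y, pd.DataFrame(index=range(5)))
        assert np.allclose(res.fittedvalues, 0.6)

    def test_duplicated_column_same_llf(self):
        y, X = logit_design()
        res_plain = ResponseModel(y, X).fit()
        X_dup = X.copy()
        X_dup["x_copy"] = X["x"]
        with pytest.warns(UserWarning, match="collinear"):
            res_dup = ResponseModel(y, X_dup).fit()
        assert res_dup.llf == pytest.approx(res_plain.llf, abs=1e-8)

    def test_llf_matches_plugin_oracle(self):
        """Reported log-likelihood equals the Bernoulli formula evaluated
        directly at the fitted coefficients (hand dataset)."""
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1])
        X = pd.DataFrame({"x": [-2, -1.5, -1, -1, -0.5, 0, 0, 0.5, 1, 1, 1.5, 2]})
        res = ResponseModel(y, X).fit()
        design = np.column_stack([np.ones(12), X["x"]])
        p = expit(design @ res.params.to_numpy())
        oracle = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert res.llf == pytest.approx(oracle, abs=1e-10)
        assert res.llf >= res.llnull

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            ResponseModel(np.ones(10), pd.DataFrame({"x": np.arange(10)}))

    def test_separation_flagged_and_capped(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        X = pd.DataFrame({"x": np.arange(8.0)})
        with pytest.warns(UserWarning, match="separation"):
            res = ResponseModel(y, X).fit()
        assert res.separation
        assert np.isfinite(res.params).all()

    def test_affine_rescaling_invariance(self):
        y, X = logit_design(seed=3)
        res = ResponseModel(y, X).fit()
        X_scaled = X.copy()
        X_scaled["x"] = 10.0 * X["x"] + 5.0
        res_scaled = ResponseModel(y, X_scaled).fit()
        assert res_scaled.llf == pytest.approx(res.llf, abs=1e-6)

    def test_summary_mentions_mcfadden(self):
        y, X = logit_design(seed=4)
        text = ResponseModel(y, X).fit().summary()
        assert "McFadden" in text and "log-likelihood" in text


class TestMcFadden:
    def test_null_model_is_zero(self):
        y = np.array([1, 0, 1, 0, 1])
        res = fit_logistic(y, pd.DataFrame(index=range(5)))
        assert mcfadden_r2(res) == pytest.approx(0.0, abs=1e-10)

    def test_near_separation_approaches_one(self):
        y = np.repeat([0, 1], 20)
        X = pd.DataFrame({"x": np.concatenate([np.random.default_rng(0).normal(-8, 1, 20),
                                               np.random.default_rng(1).normal(8, 1, 20)])})
        res = ResponseModel(y, X).fit()
        assert mcfadden_r2(res) > 0.95

    def test_formula_plugin_oracle(self):
        y, X = logit_design(seed=5)
        res = ResponseModel(y, X).fit()
        assert mcfadden_r2(res) == pytest.approx(1 - res.llf / res.llnull)

    def test_monotone_under_nesting(self):
        y, X = logit_design(seed=6)
        small = ResponseModel(y, X[["x"]]).fit()
        large = ResponseModel(y, X).fit()
        assert mcfadden_r2(large) >= mcfadden_r2(small) - 1e-10


class TestDeltaR2:
    def test_orthogonal_grs_contributes_nothing(self):
        rng = np.random.default_rng(2)
        cov = rng.normal(size=(200, 2))
        y = cov @ np.array([1.0, -0.5]) + rng.normal(size=200)
        # residualize a candidate score against y and the covariates
        grs = rng.normal(size=200)
        design = np.column_stack([np.ones(200), cov, y])
        beta, *_ = np.linalg.lstsq(design, grs, rcond=None)
        grs_orth = grs - design @ beta
        assert delta_r2(y, cov, grs_orth) == pytest.approx(0.0, abs=1e-10)

    def test_exact_linear_function_explains_all(self):
        grs = np.arange(30.0)
        y = 2.0 * grs - 5.0
        assert delta_r2(y, np.empty((30, 0)), grs) == pytest.approx(1.0)

    def test_closed_form_variance_decomposition(self):
        """Simulated beta*GRS + noise matches beta^2 Var / (beta^2 Var + sigma^2)."""
        rng = np.random.default_rng(8)
        n, beta, sigma = 6000, 0.7, 1.3
        grs = rng.normal(0, 2.0, size=n)
        cov = rng.normal(size=(n, 2))  # orthogonal covariates, no true effect
        y = beta * grs + sigma * rng.normal(size=n)
        expected = (beta**2 * 4.0) / (beta**2 * 4.0 + sigma**2)
        assert delta_r2(y, cov, grs) == pytest.approx(expected, abs=0.03)

    def test_never_negative(self):
        rng = np.random.default_rng(10)
        for seed in range(5):
            y = rng.normal(size=50)
            cov = rng.normal(size=(50, 3))
            grs = rng.normal(size=50)
            assert delta_r2(y, cov, grs) >= 0.0


class TestGroupTtest:
    def test_identical_groups(self):
        stat, p = group_ttest([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_shifted_normals_significant(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 500)
        b = rng.normal(1, 1, 500)
        _, p = group_ttest(a, b)
        assert p < 1e-3

    def test_welch_hand_oracle(self):
        a = np.array([3.1, 2.8, 3.5, 3.0, 2.9])
        b = np.array([2.1, 2.4, 2.0, 2.6, 2.3])
        mean_a, mean_b = a.mean(), b.mean()
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t = (mean_a - mean_b) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        p = 2 * stats.t.sf(abs(t), df)
        stat, pval = group_ttest(a, b)
        assert stat == pytest.approx(t)
        assert pval == pytest.approx(p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_ttest([1.0], [2.0, 3.0])


def mixed_ml_oracle(baseline, post, dosage):
    """Direct ML fit of the two-visit random-intercept model.

    y_iv = b0 + b1*post + b2*g + b3*g*post + u_i + e_iv with
    u_i ~ N(0, s2_u), e_iv ~ N(0, s2_e).  Returns the interaction
    estimate b3 and the likelihood-ratio p-value for b3 = 0.
    """
    n = len(dosage)
    y = np.concatenate([baseline, post])
    visit = np.concatenate([np.zeros(n), np.ones(n)])
    g = np.concatenate([dosage, dosage])
    subject = np.concatenate([np.arange(n), np.arange(n)])

    def neg_loglik(theta, X):
        s2_u, s2_e = np.exp(theta)
        # block-diagonal 2x2 covariance per subject
        var = s2_u + s2_e
        cov = s2_u
        det = var**2 - cov**2
        inv = np.array([[var, -cov], [-cov, var]]) / det
        # GLS for beta
        XtX = np.zeros((X.shape[1], X.shape[1]))
        Xty = np.zeros(X.shape[1])
        for i in range(n):
            idx = subject == i
            Xi, yi = X[idx], y[idx]
            XtX += Xi.T @ inv @ Xi
            Xty += Xi.T @ inv @ yi
        beta = np.linalg.solve(XtX, Xty)
        ll = 0.0
        for i in range(n):
            idx = subject == i
            r = y[idx] - X[idx] @ beta
            ll += -0.5 * (np.log(det) + r @ inv @ r + 2 * np.log(2 * np.pi))
        return -ll, beta

    def fit(X):
        best = None
        res = optimize.minimize(
            lambda th: neg_loglik(th, X)[0], x0=[np.log(0.5), np.log(0.5)],
            method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}
        )
        nll, beta = neg_loglik(res.x, X)
        return nll, beta

    X_full = np.column_stack([np.ones(2 * n), visit, g, g * visit])
    X_null = X_full[:, :3]
    nll_full, beta_full = fit(X_full)
    nll_null, _ = fit(X_null)
    lr = 2 * (nll_null - nll_full)
    return beta_full[3], stats.chi2.sf(max(lr, 0.0), df=1)


class TestSnpVisitInteraction:
    def toy_data(self, n=60, effect=0.4, seed=13):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.3, size=n).astype(float)
        u = rng.normal(0, 0.5, size=n)
        baseline = 1.5 + u + rng.normal(0, 0.3, size=n)
        post = 1.5 - 0.2 + effect * g + u + rng.normal(0, 0.3, size=n)
        return baseline, post, g

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            snp_visit_interaction(np.ones(10), np.ones(10), np.zeros(10))

    def test_change_score_equals_mixed_ml_oracle(self):
        """The change-score genotype coefficient reproduces the explicit
        two-visit random-intercept ML interaction estimate, and the LR
        p-value agrees with the change-score t-test."""
        baseline, post, g = self.toy_data()
        p, details = snp_visit_interaction(baseline, post, g, return_details=True)
        b3_ml, p_lr = mixed_ml_oracle(baseline, post, g)
        assert details["coef"] == pytest.approx(b3_ml, abs=1e-6)
        assert p == pytest.approx(p_lr, abs=0.02)

    def test_power_increases_with_effect(self):
        p_small = snp_visit_interaction(*self.toy_data(effect=0.05, seed=21))
        p_large = snp_visit_interaction(*self.toy_data(effect=0.8, seed=21))
        assert p_large < p_small

    def test_covariates_accepted(self):
        baseline, post, g = self.toy_data()
        rng = np.random.default_rng(0)
        cov = rng.normal(size=(60, 3))
        p = snp_visit_interaction(baseline, post, g, covariates=cov)
        assert 0 <= p <= 1
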