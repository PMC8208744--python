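"""Beta regression likelihood, fitting and the quasi-binomial fallback."""

import math

import numpy as np
import pytest
from scipy import optimize
from scipy.special import expit, logit

from apareg.regression import (
    BetaRegression,
    QuasiBinomialRegression,
    beta_loglik,
    fit_beta_regression,
    fit_quasibinomial,
)


def brute_force_max(r, X, n_starts=6, seed=0):
    """Independent oracle: multi-start Nelder-Mead maximization of the
    beta log-likelihood over (beta, log phi)."""
    rng = np.random.default_rng(seed)
    p = X.shape[1]
    best = -np.inf
    best_x = None
    starts = [np.zeros(p + 1), np.r_[np.zeros(p), 3.0]]
    starts += [rng.normal(0, 1, p + 1) + np.r_[np.zeros(p), 2.0]
               for _ in range(n_starts - 2)]
    for x0 in starts:
        res = optimize.minimize(
            lambda t: -beta_loglik(t[:-1], math.exp(t[-1]), r, X), x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000,
                     "maxfev": 20000},
        )
        if -res.fun > best:
            best, best_x = -res.fun, res.x
    return best, best_x


class TestBetaLoglik:
    def test_uniform_density_case(self):
        # Beta(1,1) has density 1 everywhere: phi=2, mu=1/2
        assert beta_loglik([0.0], 2.0, [0.5], [[1.0]]) == pytest.approx(0.0)

    def test_symmetric_beta_density_value(self):
        # Beta(2,2) density at 1/2 is 1.5
        assert beta_loglik([0.0], 4.0, [0.5], [[1.0]]) == pytest.approx(
            math.log(1.5))

    def test_matches_scipy_beta_density(self, rng):
        from scipy.stats import beta as beta_dist
        X = np.column_stack([np.ones(8), rng.normal(size=8)])
        b, phi = np.array([-0.5, 0.8]), 23.0
        r = rng.beta(2, 5, size=8)
        mu = expit(X @ b)
        expected = beta_dist.logpdf(r, mu * phi, (1 - mu) * phi).sum()
        assert beta_loglik(b, phi, r, X) == pytest.approx(expected)

    def test_mirror_symmetry_of_beta_family(self, rng):
        X = np.ones((10, 1))
        r = rng.beta(3, 6, size=10)
        ll = beta_loglik([0.7], 15.0, r, X)
        ll_flip = beta_loglik([-0.7], 15.0, 1 - r, X)
        assert ll == pytest.approx(ll_flip)

    def test_boundary_ratio_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            beta_loglik([0.0], 2.0, [0.0, 0.5], [[1.0], [1.0]])


class TestBetaRegression:
    def test_intercept_only_mean_near_sample_mean(self):
        m = BetaRegression().fit(np.empty((3, 0)), [0.2, 0.25, 0.3])
        assert 0.2 < expit(m.intercept_) < 0.3
        assert expit(m.intercept_) == pytest.approx(0.25, abs=0.01)

    def test_optimum_matches_bruteforce(self):
        # grid/simplex oracle on the intercept-only model
        y = np.array([0.2, 0.25, 0.3])
        X = np.ones((3, 1))
        m = BetaRegression(fit_intercept=False).fit(X, y)
        ll_oracle, x_oracle = brute_force_max(y, X)
        assert m.loglik_ == pytest.approx(ll_oracle, rel=1e-6, abs=1e-8)
        assert m.params_[0] == pytest.approx(x_oracle[0], abs=1e-4)

    def test_matches_statsmodels_betamodel(self, rng):
        """Independent cross-check against the reference ML implementation."""
        import statsmodels.api as sm
        from statsmodels.othermod.betareg import BetaModel

        X = rng.normal(size=(40, 2))
        mu = expit(0.3 + X @ [1.0, -0.5])
        y = rng.beta(mu * 30, (1 - mu) * 30)
        ours = BetaRegression().fit(X, y)
        ref = BetaModel(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(ours.params_, ref.params[:3], atol=1e-5)
        assert ours.loglik_ == pytest.approx(ref.llf, abs=1e-8)
        assert ours.phi_ == pytest.approx(math.exp(ref.params[3]), rel=1e-4)

    def test_group_label_swap_flips_sign_only(self, rng):
        X = np.r_[np.zeros(8), np.ones(8)].reshape(-1, 1)
        mu = expit(-1 + 0.8 * X[:, 0])
        y = rng.beta(mu * 40, (1 - mu) * 40)
        a = BetaRegression().fit(X, y)
        b = BetaRegression().fit(1 - X, y)
        assert a.coef_[0] == pytest.approx(-b.coef_[0], abs=1e-5)
        assert abs(a.zvalues_[1]) == pytest.approx(abs(b.zvalues_[1]), abs=1e-5)
        assert a.pvalues_[1] == pytest.approx(b.pvalues_[1], abs=1e-6)

    def test_mirror_data_negates_intercept(self, rng):
        X = rng.normal(size=(20, 1))
        mu = expit(0.5 + 0.7 * X[:, 0])
        y = rng.beta(mu * 25, (1 - mu) * 25)
        a = BetaRegression().fit(X, y)
        b = BetaRegression().fit(X, 1 - y)
        np.testing.assert_allclose(a.params_, -b.params_, atol=1e-5)
        assert a.phi_ == pytest.approx(b.phi_, rel=1e-4)

    def test_boundary_response_raises(self):
        with pytest.raises(ValueError, match="strictly in"):
            BetaRegression().fit(np.ones((4, 1)), [0.0, 0.3, 0.5, 0.7])

    def test_more_parameters_than_samples_raises(self):
        with pytest.raises(ValueError, match="more samples"):
            BetaRegression().fit(np.ones((2, 2)), [0.4, 0.5])

    def test_predict_returns_fitted_means(self, rng):
        X = rng.normal(size=(25, 1))
        mu = expit(0.2 + 1.1 * X[:, 0])
        y = rng.beta(mu * 60, (1 - mu) * 60)
        m = BetaRegression().fit(X, y)
        pred = m.predict(X)
        assert np.all((pred > 0) & (pred < 1))
        assert np.corrcoef(pred, y)[0, 1] > 0.8

    def test_sklearn_param_protocol(self):
        m = BetaRegression(tol=1e-7)
        assert m.get_params()["tol"] == 1e-7
        m.set_params(max_iter=100)
        assert m.max_iter == 100

    def test_parameter_recovery_small_sim(self, rng):
        """Estimates cluster around truth at n=20/group (50 replicates)."""
        X = np.r_[np.zeros(20), np.ones(20)].reshape(-1, 1)
        mu = expit(logit(0.2) + 1.0 * X[:, 0])
        within = 0
        for _ in range(50):
            y = rng.beta(mu * 50, (1 - mu) * 50)
            m = BetaRegression().fit(X, y)
            within += abs(m.coef_[0] - 1.0) < 3 * m.bse_[1]
        assert within >= 47  # ~99.7% nominal; allow sampling slack


class TestQuasiBinomial:
    def test_no_signal_gives_null_coefficient(self):
        X = np.r_[np.zeros(3), np.ones(3)].reshape(-1, 1)
        counts = np.tile([20.0, 80.0], (6, 1))  # identical in every sample
        m = fit_quasibinomial(counts, X)
        assert m.coef_[0] == pytest.approx(0.0, abs=1e-8)
        assert m.pvalues_[1] == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_long_is_untestable(self):
        X = np.r_[np.zeros(3), np.ones(3)].reshape(-1, 1)
        counts = np.column_stack([np.zeros(6), np.full(6, 50.0)])
        m = fit_quasibinomial(counts, X)
        assert not m.testable_

    def test_irls_matches_deviance_minimization(self):
        """Coefficients agree with direct minimization of the binomial
        deviance (independent oracle)."""
        n_long = np.array([10.0, 20.0, 50.0, 60.0])
        n_short = np.array([90.0, 80.0, 50.0, 40.0])
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        m = fit_quasibinomial(np.column_stack([n_long, n_short]), X)

        total = n_long + n_short
        design = np.column_stack([np.ones(4), X[:, 0]])

        def deviance(b):
            mu = expit(design @ b)
            return -np.sum(n_long * np.log(mu) + n_short * np.log(1 - mu))

        oracle = optimize.minimize(deviance, [0.0, 0.0], method="Nelder-Mead",
                                   options={"xatol": 1e-12, "fatol": 1e-12})
        np.testing.assert_allclose(m.params_, oracle.x, atol=1e-6)

    def test_dispersion_is_pearson_over_df(self, rng):
        X = rng.normal(size=(12, 1))
        totals = np.full(12, 100.0)
        y = rng.binomial(100, expit(0.3 * X[:, 0])) / 100.0
        m = QuasiBinomialRegression().fit(X, y, totals=totals)
        mu = m.predict(X)
        pearson = np.sum(totals * (y - mu) ** 2 / (mu * (1 - mu)))
        assert m.dispersion_ == pytest.approx(pearson / (12 - 2), rel=1e-6)

    def test_zero_total_samples_dropped(self):
        X = np.r_[np.zeros(3), np.ones(3)].reshape(-1, 1)
        counts = np.array([[10, 30], [12, 28], [0, 0], [20, 20], [22, 18],
                           [18, 22]], dtype=float)
        m = fit_quasibinomial(counts, X)
        assert m.df_resid_ == 5 - 2


class TestFallbackConsistency:
    def test_beta_and_qb_signs_agree_on_informative_pairs(self, rng):
        """On boundary-free data the two model paths agree in direction."""
        X = np.r_[np.zeros(5), np.ones(5)].reshape(-1, 1)
        agree = total = 0
        for _ in range(100):
            totals = np.maximum(
                rng.negative_binomial(1 / 0.3, (1 / 0.3) / (1 / 0.3 + 200),
                                      size=10), 1)
            p = expit(logit(0.2) + np.log(2.5) * X[:, 0])
            n_long = rng.binomial(totals, p)
            r = n_long / totals
            if np.any((r == 0) | (r == 1)):
                continue
            total += 1
            b = BetaRegression().fit(X, r)
            q = QuasiBinomialRegression().fit(X, r, totals=totals.astype(float))
            agree += np.sign(b.coef_[0]) == np.sign(q.coef_[0])
        assert agree / total >= 0.95
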