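"""Beta regression and quasi-binomial GLM for isoform-ratio responses.

The beta regression models a ratio R in (0,1) as Beta-distributed with
mean mu linked to covariates through a logit link and a single precision
parameter phi shared across samples:

    R_j ~ Beta(mu_j * phi, (1 - mu_j) * phi),   logit(mu_j) = x_j' beta

Maximum likelihood is computed by quasi-Newton optimization of the exact
log-likelihood with analytic gradients, parameterizing phi on the log
scale; standard errors come from the inverse of the negative Hessian at
the optimum.  Ratios exactly at 0 or 1 are outside the beta support; those
pairs are handled by a logistic-link quasi-binomial GLM with totals as
prior weights, free Pearson dispersion and t-based inference.

Both models follow the scikit-learn estimator protocol (``fit``,
``predict``, ``get_params``/``set_params``, fitted attributes with a
trailing underscore) so they compose with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted


def beta_loglik(beta, phi: float, ratios, X) -> float:
    """Log-likelihood of the logit-link beta regression.

    Parameters are the mean-model coefficients ``beta`` (matching the
    columns of ``X``, which must already include any intercept), the
    precision ``phi`` > 0, and responses ``ratios`` strictly in (0,1).
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if np.any((r <= 0) | (r >= 1)):
        raise ValueError("beta log-likelihood undefined for ratios at 0 or 1")
    if phi <= 0:
        raise ValueError("precision phi must be positive")
    mu = special.expit(X @ beta)
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(mu * phi)
            - special.gammaln((1 - mu) * phi)
            + (mu * phi - 1) * np.log(r)
            + ((1 - mu) * phi - 1) * np.log1p(-r)
        )
    )


def _negloglik_and_grad(theta, r, X, ystar, log_r, log_1mr):
    """Negative log-likelihood and gradient in (beta, log phi)."""
    beta, logphi = theta[:-1], theta[-1]
    phi = np.exp(logphi)
    eta = X @ beta
    mu = special.expit(eta)
    a, b = mu * phi, (1 - mu) * phi
    ll = np.sum(
        special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
        + (a - 1) * log_r + (b - 1) * log_1mr
    )
    mustar = special.digamma(a) - special.digamma(b)
    w = mu * (1 - mu)  # d mu / d eta for the logit link
    grad_beta = phi * (X.T @ ((ystar - mustar) * w))
    dphi = np.sum(
        special.digamma(phi) - mu * special.digamma(a)
        - (1 - mu) * special.digamma(b) + mu * log_r + (1 - mu) * log_1mr
    )
    grad = np.concatenate([grad_beta, [dphi * phi]])  # chain rule for log phi
    return -ll, -grad


def _numerical_hessian(fun, theta, eps=1e-5):
    """Central finite differences of an analytic gradient."""
    k = theta.size
    H = np.empty((k, k))
    for i in range(k):
        step = np.zeros(k)
        step[i] = eps * max(1.0, abs(theta[i]))
        _, gp = fun(theta + step)
        _, gm = fun(theta - step)
        H[i] = (gp - gm) / (2 * step[i])
    return (H + H.T) / 2


class BetaRegression(RegressorMixin, BaseEstimator):
    """Maximum-likelihood beta regression with logit mean link.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend a constant column to the design.
    tol : float, default 1e-8
        Optimizer gradient tolerance.
    max_iter : int, default 500
        Optimizer iteration cap.
    inference : {'wald-t', 'wald-normal'}, default 'wald-t'
        'wald-t' applies a small-sample correction: the ML precision
        estimate is biased upward at small n (it ignores the p mean
        parameters already fitted), which shrinks standard errors and
        inflates type-I error.  Standard errors are rescaled by
        sqrt(n / (n - p)) and coefficients referred to a t distribution
        on n - p df.  'wald-normal' is the uncorrected asymptotic test.

    Attributes
    ----------
    params_ : full coefficient vector (intercept first when fitted).
    intercept_, coef_ : sklearn-style split of ``params_``.
    phi_ : estimated precision (> 0).
    bse_ : standard errors of ``params_`` from the observed information.
    loglik_ : log-likelihood at the optimum.
    converged_ : whether the optimizer met its tolerances.
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8,
                 max_iter: int = 500, inference: str = "wald-t"):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.inference = inference

    def _design(self, X):
        X = check_array(X, dtype=float, ensure_2d=True,
                        ensure_min_features=0 if self.fit_intercept else 1)
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def fit(self, X, y):
        X = self._design(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != len(X):
            raise ValueError("X and y have inconsistent lengths")
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError(
                "beta regression requires responses strictly in (0,1); "
                "route boundary ratios to the quasi-binomial model"
            )
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need more samples ({n}) than parameters ({p})")

        # init: least squares on the logit scale, method-of-moments phi
        ylogit = special.logit(np.clip(y, 1e-6, 1 - 1e-6))
        beta0, *_ = np.linalg.lstsq(X, ylogit, rcond=None)
        mu0 = special.expit(X @ beta0)
        resid = y - mu0
        var0 = max(float(np.var(resid, ddof=min(p, n - 1))), 1e-8)
        phi0 = max(float(np.mean(mu0 * (1 - mu0)) / var0 - 1), 1.0)

        log_r, log_1mr = np.log(y), np.log1p(-y)
        ystar = log_r - log_1mr
        args = (y, X, ystar, log_r, log_1mr)
        theta0 = np.concatenate([beta0, [np.log(phi0)]])
        if self.inference not in ("wald-t", "wald-normal"):
            raise ValueError(f"unknown inference {self.inference!r}")
        res = optimize.minimize(
            _negloglik_and_grad, theta0, args=args, jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.tol, "ftol": 1e-13},
        )
        theta = res.x
        # judge convergence by the score at the solution, not the line
        # search's exit status
        _, grad = _negloglik_and_grad(theta, *args)
        self.converged_ = bool(
            res.success or np.max(np.abs(grad)) < 1e-4 * (1.0 + abs(res.fun))
        )
        self.params_ = theta[:-1].copy()
        self.phi_ = float(np.exp(theta[-1]))
        self.loglik_ = -float(res.fun)
        if self.fit_intercept:
            self.intercept_, self.coef_ = self.params_[0], self.params_[1:]
        else:
            self.intercept_, self.coef_ = 0.0, self.params_

        H = _numerical_hessian(lambda t: _negloglik_and_grad(t, *args), theta)
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov))
            if np.any(~np.isfinite(se)):
                raise np.linalg.LinAlgError
            self.covariance_ = cov[:-1, :-1]
            self.bse_ = se[:-1]
        except np.linalg.LinAlgError:
            self.covariance_ = np.full((p, p), np.nan)
            self.bse_ = np.full(p, np.nan)
            self.converged_ = False
        self.df_resid_ = n - p
        if self.inference == "wald-t":
            correction = np.sqrt(n / self.df_resid_)
            self.bse_ = self.bse_ * correction
            self.covariance_ = self.covariance_ * correction**2
        with np.errstate(invalid="ignore", divide="ignore"):
            self.zvalues_ = self.params_ / self.bse_
        if self.inference == "wald-t":
            self.pvalues_ = 2 * stats.t.sf(np.abs(self.zvalues_), self.df_resid_)
        else:
            self.pvalues_ = 2 * stats.norm.sf(np.abs(self.zvalues_))
        self.n_features_in_ = X.shape[1] - int(self.fit_intercept)
        return self

    def predict(self, X):
        """Fitted mean long-isoform proportion."""
        check_is_fitted(self, "params_")
        return special.expit(self._design(X) @ self.params_)

    def loglik_null(self, X, y, drop: int):
        """Log-likelihood with column ``drop`` of the full design removed
        (for likelihood-ratio tests); returns the restricted fit."""
        Xd = np.delete(self._design(X), drop, axis=1)
        sub = BetaRegression(fit_intercept=False, tol=self.tol,
                             max_iter=self.max_iter)
        return sub.fit(Xd, y)


def fit_beta_regression(ratios, X, fit_intercept: bool = True) -> BetaRegression:
    """Functional wrapper over :class:`BetaRegression`."""
    return BetaRegression(fit_intercept=fit_intercept).fit(X, ratios)


class QuasiBinomialRegression(RegressorMixin, BaseEstimator):
    """Logistic-link GLM for proportions with free dispersion.

    Fitted by iteratively reweighted least squares on the per-sample
    ratios with the short+long totals as prior weights; the dispersion is
    the Pearson chi-square divided by the residual degrees of freedom and
    inference on coefficients uses t statistics on n - p df.

    Attributes mirror :class:`BetaRegression`; ``dispersion_`` replaces
    ``phi_``.  ``testable_`` is False under separation or an all-boundary
    response, where the MLE diverges.
    """

    # coefficients beyond this magnitude on the logit scale indicate
    # separation / boundary divergence
    _DIVERGENCE_BOUND = 25.0

    def __init__(self, fit_intercept: bool = True, max_iter: int = 100):
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter

    def fit(self, X, y, totals=None):
        """Fit on ratios ``y`` with prior weights ``totals``.

        ``y`` may instead be an (n, 2) array of (n_long, n_short) counts,
        in which case totals are derived.
        """
        import statsmodels.api as sm

        X = check_array(X, dtype=float, ensure_2d=True)
        y = np.asarray(y, dtype=float)
        if y.ndim == 2:
            if y.shape[1] != 2:
                raise ValueError("count input must have columns (n_long, n_short)")
            totals = y.sum(axis=1)
            with np.errstate(invalid="ignore"):
                y = np.where(totals > 0, y[:, 0] / np.where(totals > 0, totals, 1), np.nan)
        if totals is None:
            raise ValueError("totals (prior weights) are required for ratio input")
        totals = np.asarray(totals, dtype=float)
        keep = totals > 0
        if not np.any(keep):
            raise ValueError("no sample with positive total count")
        X, y, totals = X[keep], y[keep], totals[keep]
        design = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        n, p = design.shape
        if n <= p:
            raise ValueError(f"need more samples ({n}) than parameters ({p})")
        self.df_resid_ = n - p
        self.n_features_in_ = p - int(self.fit_intercept)

        if np.all(y == y[0]):
            # constant response: the MLE is exact with zero residual
            # variation; at the boundary (all long counts zero, say) the
            # intercept diverges and the pair is untestable
            if y[0] in (0.0, 1.0):
                self.params_ = np.full(p, np.nan)
                self.params_[0] = -np.inf if y[0] == 0.0 else np.inf
                self.bse_ = np.full(p, np.nan)
                self.dispersion_ = 0.0
                self.converged_ = True
                self.testable_ = False
            else:
                self.params_ = np.zeros(p)
                self.params_[0] = special.logit(y[0])
                self.bse_ = np.zeros(p)
                self.dispersion_ = 0.0
                self.converged_ = True
                self.testable_ = True
            with np.errstate(invalid="ignore", divide="ignore"):
                self.tvalues_ = self.params_ / self.bse_
            self.pvalues_ = np.where(self.params_ == 0.0, 1.0, np.nan)
            self._split_params()
            return self

        import warnings as _warnings
        with np.errstate(all="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            model = sm.GLM(y, design, family=sm.families.Binomial(),
                           var_weights=totals)
            res = model.fit(scale="X2", maxiter=self.max_iter)
        self.params_ = np.asarray(res.params)
        self.dispersion_ = float(res.scale)
        self.bse_ = np.asarray(res.bse)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.tvalues_ = self.params_ / self.bse_
        self.pvalues_ = 2 * stats.t.sf(np.abs(self.tvalues_), self.df_resid_)
        self.converged_ = bool(getattr(res, "converged", True))
        self.testable_ = bool(
            np.all(np.isfinite(self.params_))
            and np.all(np.isfinite(self.bse_))
            and self.dispersion_ > 0
            and np.all(np.abs(self.params_) < self._DIVERGENCE_BOUND)
        )
        self._split_params()
        return self

    def _split_params(self) -> None:
        if self.fit_intercept:
            self.intercept_, self.coef_ = self.params_[0], self.params_[1:]
        else:
            self.intercept_, self.coef_ = 0.0, self.params_

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float, ensure_2d=True)
        design = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        return special.expit(design @ self.params_)


def fit_quasibinomial(counts, X, fit_intercept: bool = True) -> QuasiBinomialRegression:
    """Functional wrapper: ``counts`` is an (n, 2) array of (n_long, n_short)."""
    return QuasiBinomialRegression(fit_intercept=fit_intercept).fit(X, counts)
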