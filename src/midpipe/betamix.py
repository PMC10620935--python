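"""Beta regression with a Gaussian random intercept, fit by maximum likelihood.

Isotopologue fractions live on (0, 1), so group differences are modeled
with a beta likelihood parameterized by mean and precision,

    y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi),
    logit(mu_i) = x_i' beta + b_{donor(i)},      b_d ~ Normal(0, sigma_d^2),

with the donor random intercept absorbing the within-donor correlation of
repeatedly sampled cells.  The marginal likelihood integrates b out per
donor by adaptive Gauss-Hermite quadrature: nodes are centered at the
per-donor posterior mode and scaled by the curvature there, which keeps a
modest node count accurate even for large phi.  Fixed effects, log(phi)
and log(sigma_d) are maximized jointly with L-BFGS-B; standard errors
come from the numerically differentiated observed information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from numpy.polynomial.hermite import hermgauss
from scipy.special import betaln, digamma, expit, logsumexp, polygamma

_MU_EPS = 1e-12
_LOG_SIGMA_FLOOR = np.log(1e-8)


def shrink_boundary(y: np.ndarray) -> np.ndarray:
    """Map boundary observations into (0, 1) by y' = (y*(N-1) + 0.5)/N.

    Only exact 0/1 values are moved; interior fractions are returned
    unchanged.  N is the number of observations.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    out = y.copy()
    at_boundary = (y <= 0.0) | (y >= 1.0)
    out[at_boundary] = (y[at_boundary] * (n - 1) + 0.5) / n
    return out


def _beta_loglik_obs(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    a = mu * phi
    b = (1.0 - mu) * phi
    return (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)


@dataclass
class BetaMixedResult:
    """MLE of the donor-random-intercept beta regression."""

    params: pd.Series           # fixed effects on the logit scale, by design column
    phi: float                  # precision
    sigma_d: float              # donor random-intercept SD
    cov_params: pd.DataFrame    # covariance of the fixed effects
    loglik: float
    converged: bool
    degenerate: bool = False    # all observations at one boundary pre-shrinkage
    n_obs: int = 0
    df_resid: float = np.inf    # residual df for the t reference of Wald tests
    message: str = ""


class BetaMixedModel:
    """Marginal-likelihood machinery for one analyte's fraction data.

    Parameters
    ----------
    y : observations in (0, 1) (apply :func:`shrink_boundary` first).
    X : design matrix (n x k), typically one-hot group indicators.
    donor : donor label per observation; defines the integration blocks.
    n_quad : Gauss-Hermite node count (>= 9 recommended).
    """

    def __init__(self, y, X, donor, n_quad: int = 15):
        self.y = np.asarray(y, dtype=float)
        if np.any((self.y <= 0) | (self.y >= 1)):
            raise ValueError("y must lie strictly in (0, 1); use shrink_boundary")
        self.X = np.asarray(X, dtype=float)
        self.columns = list(X.columns) if hasattr(X, "columns") else [
            f"x{i}" for i in range(self.X.shape[1])
        ]
        codes, uniques = pd.factorize(np.asarray(donor))
        self.donor_idx = codes
        self.n_donors = len(uniques)
        self.n_quad = int(n_quad)
        self.logit_y = np.log(self.y) - np.log1p(-self.y)

    # ---- likelihood ------------------------------------------------------

    def _eta_parts(self, beta: np.ndarray) -> np.ndarray:
        return self.X @ beta

    def _donor_sum(self, values: np.ndarray) -> np.ndarray:
        return np.bincount(self.donor_idx, weights=values, minlength=self.n_donors)

    def _mode_and_curvature(
        self, xb: np.ndarray, phi: float, sigma: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-donor posterior mode of b and curvature of log-integrand there."""
        b = np.zeros(self.n_donors)
        for _ in range(100):
            eta = xb + b[self.donor_idx]
            mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
            m = mu * (1.0 - mu)
            s = self.logit_y - digamma(mu * phi) + digamma((1.0 - mu) * phi)
            g_obs = phi * m * s
            trig = polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi)
            h_obs = phi * (m * (1.0 - 2.0 * mu) * s - phi * m**2 * trig)
            grad = self._donor_sum(g_obs) - b / sigma**2
            hess = self._donor_sum(h_obs) - 1.0 / sigma**2
            hess = np.minimum(hess, -1e-10)  # log-concave in practice; guard anyway
            step = grad / hess
            # dampen large steps for stability at extreme phi
            step = np.clip(step, -5.0, 5.0)
            b_new = b - step
            if np.max(np.abs(b_new - b)) < 1e-10:
                b = b_new
                break
            b = b_new
        eta = xb + b[self.donor_idx]
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        m = mu * (1.0 - mu)
        s = self.logit_y - digamma(mu * phi) + digamma((1.0 - mu) * phi)
        trig = polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi)
        h_obs = phi * (m * (1.0 - 2.0 * mu) * s - phi * m**2 * trig)
        curv = self._donor_sum(h_obs) - 1.0 / sigma**2
        curv = np.minimum(curv, -1e-10)
        return b, curv

    def loglik(
        self, beta: np.ndarray, phi: float, sigma_d: float, n_quad: int | None = None
    ) -> float:
        """Marginal log-likelihood, donors integrated out by adaptive quadrature."""
        beta = np.asarray(beta, dtype=float)
        xb = self._eta_parts(beta)
        if sigma_d < 1e-7:
            mu = np.clip(expit(xb), _MU_EPS, 1.0 - _MU_EPS)
            return float(np.sum(_beta_loglik_obs(self.y, mu, phi)))
        nq = self.n_quad if n_quad is None else int(n_quad)
        nodes, weights = hermgauss(nq)
        b_hat, curv = self._mode_and_curvature(xb, phi, sigma_d)
        omega = 1.0 / np.sqrt(-curv)
        log_norm = -0.5 * np.log(2.0 * np.pi) - np.log(sigma_d)
        terms = np.empty((nq, self.n_donors))
        for k in range(nq):
            b_k = b_hat + np.sqrt(2.0) * omega * nodes[k]
            eta = xb + b_k[self.donor_idx]
            mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
            ll_obs = self._donor_sum(_beta_loglik_obs(self.y, mu, phi))
            ll_prior = -0.5 * (b_k / sigma_d) ** 2 + log_norm
            terms[k] = np.log(weights[k]) + nodes[k] ** 2 + ll_obs + ll_prior
        per_donor = logsumexp(terms, axis=0) + 0.5 * np.log(2.0) + np.log(omega)
        return float(np.sum(per_donor))

    # ---- fitting ---------------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> tuple[np.ndarray, float, float]:
        k = len(self.columns)
        return theta[:k], float(np.exp(theta[k])), float(np.exp(theta[k + 1]))

    def _neg_loglik(self, theta: np.ndarray) -> float:
        beta, phi, sigma = self._unpack(theta)
        ll = self.loglik(beta, phi, sigma)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    def _start(self) -> np.ndarray:
        beta0, *_ = np.linalg.lstsq(self.X, self.logit_y, rcond=None)
        mu0 = np.clip(expit(self.X @ beta0), 1e-6, 1 - 1e-6)
        resid = self.y - mu0
        v = max(float(np.var(resid)), 1e-8)
        phi0 = max(float(np.mean(mu0 * (1 - mu0)) / v) - 1.0, 2.0)
        return np.concatenate([beta0, [np.log(phi0), np.log(0.1)]])

    def fit(self, maxiter: int = 300) -> BetaMixedResult:
        theta0 = self._start()
        k = len(self.columns)
        bounds = [(None, None)] * k + [
            (np.log(1e-2), np.log(1e8)),
            (_LOG_SIGMA_FLOOR, np.log(50.0)),
        ]
        res = scipy.optimize.minimize(
            self._neg_loglik,
            theta0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-8},
        )
        beta, phi, sigma = self._unpack(res.x)
        cov = self._cov_beta(res.x)
        return BetaMixedResult(
            params=pd.Series(beta, index=self.columns),
            phi=phi,
            sigma_d=0.0 if res.x[k + 1] <= _LOG_SIGMA_FLOOR + 1e-9 else sigma,
            cov_params=pd.DataFrame(cov, index=self.columns, columns=self.columns),
            loglik=-res.fun,
            converged=bool(res.success),
            n_obs=self.y.size,
            message=str(res.message),
        )

    def _cov_beta(self, theta: np.ndarray) -> np.ndarray:
        """Fixed-effect covariance from the observed information (central differences)."""
        p = len(theta)
        h = np.maximum(1e-4, 1e-4 * np.abs(theta))
        H = np.zeros((p, p))
        f0 = self._neg_loglik(theta)
        for i in range(p):
            for j in range(i, p):
                ti = np.zeros(p)
                ti[i] = h[i]
                tj = np.zeros(p)
                tj[j] = h[j]
                if i == j:
                    fpp = self._neg_loglik(theta + ti)
                    fmm = self._neg_loglik(theta - ti)
                    H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
                else:
                    fpp = self._neg_loglik(theta + ti + tj)
                    fpm = self._neg_loglik(theta + ti - tj)
                    fmp = self._neg_loglik(theta - ti + tj)
                    fmm = self._neg_loglik(theta - ti - tj)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
        k = len(self.columns)
        try:
            cov_all = np.linalg.inv(H)
            cov = cov_all[:k, :k]
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            # fall back to inverting the beta block alone
            cov = np.linalg.pinv(H[:k, :k])
        return cov


def fit_beta_mixed(
    y, X, donor, n_quad: int = 15, maxiter: int = 300
) -> BetaMixedResult:
    """Convenience wrapper: shrink boundaries, build the model, fit it.

    Flags the fit as degenerate (and skips optimization) when every
    observation sits at the same boundary, where the group difference is
    unidentifiable.
    """
    y = np.asarray(y, dtype=float)
    if np.all(y <= 0.0) or np.all(y >= 1.0):
        k = X.shape[1]
        cols = list(X.columns) if hasattr(X, "columns") else [f"x{i}" for i in range(k)]
        return BetaMixedResult(
            params=pd.Series(np.nan, index=cols),
            phi=np.nan,
            sigma_d=np.nan,
            cov_params=pd.DataFrame(np.nan, index=cols, columns=cols),
            loglik=np.nan,
            converged=False,
            degenerate=True,
            n_obs=y.size,
            message="all observations at one boundary",
        )
    model = BetaMixedModel(shrink_boundary(y), X, donor, n_quad=n_quad)
    result = model.fit(maxiter=maxiter)
    k = len(model.columns)
    result.df_resid = float(max(y.size - k - (model.n_donors - 1) - 1, 1))
    return result
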