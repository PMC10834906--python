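"""Maximum likelihood for a binomial logit model with one Gaussian random
intercept per group, via adaptive Gauss-Hermite quadrature.

The marginal likelihood of group *i* is

    L_i(beta, sigma) = \\int prod_j Binom(y_ij | n_ij, logistic(x_ij' beta + b))
                         N(b | 0, sigma^2) db

approximated with Gauss-Hermite nodes recentred at the conditional mode of
``b`` and rescaled by the conditional curvature (adaptive quadrature).  One
node reduces to the Laplace approximation; ``sigma = 0`` reduces to the
ordinary independent-observations logistic likelihood.

Only the quadrature machinery lives here; model construction and reporting
are in :mod:`hazardlpe.psychometric`.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class BinomialRandomInterceptModel:
    """Binomial GLMM with a single random intercept, fitted by AGQ.

    Parameters
    ----------
    X : (n_obs, p) fixed-effect design matrix
    y : (n_obs,) successes
    n : (n_obs,) trials
    group_idx : (n_obs,) integer group (participant) index in [0, n_groups)
    n_quad : number of Gauss-Hermite nodes (1 = Laplace)
    """

    def __init__(self, X, y, n, group_idx, n_groups=None, n_quad=10):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.group_idx = np.asarray(group_idx, dtype=np.intp)
        self.n_groups = int(n_groups if n_groups is not None
                            else self.group_idx.max() + 1)
        self.n_obs, self.p = self.X.shape
        nodes, weights = np.polynomial.hermite.hermgauss(int(n_quad))
        self._nodes = nodes
        self._log_weights = np.log(weights) + nodes**2
        # warm-started conditional modes, reused across objective evaluations
        self._bhat = np.zeros(self.n_groups)
        #: constant sum of log binomial coefficients
        self.log_binom_const = float(
            np.sum(gammaln(self.n + 1) - gammaln(self.y + 1)
                   - gammaln(self.n - self.y + 1))
        )

    # -- likelihood pieces ------------------------------------------------

    def _rowwise_loglik(self, eta):
        return self.y * eta - self.n * np.logaddexp(0.0, eta)

    def _group_sum(self, vals):
        return np.bincount(self.group_idx, weights=vals,
                           minlength=self.n_groups)

    def _find_modes(self, eta0, sigma2, tol=1e-11, maxiter=100):
        """Newton maximization of h_i(b) = ll_i(b) - b^2 / (2 sigma^2)."""
        b = self._bhat.copy()
        for _ in range(maxiter):
            eta = eta0 + b[self.group_idx]
            p = expit(eta)
            grad = self._group_sum(self.y - self.n * p) - b / sigma2
            curv = -self._group_sum(self.n * p * (1.0 - p)) - 1.0 / sigma2
            step = grad / curv
            np.clip(step, -10.0, 10.0, out=step)
            b -= step
            if np.max(np.abs(step)) < tol:
                break
        self._bhat = b
        eta = eta0 + b[self.group_idx]
        p = expit(eta)
        curv = -self._group_sum(self.n * p * (1.0 - p)) - 1.0 / sigma2
        return b, curv

    def loglik(self, beta, sigma):
        """Marginal log likelihood (without the binomial-coefficient constant)."""
        beta = np.asarray(beta, dtype=float)
        eta0 = self.X @ beta
        if sigma <= 0.0:
            return float(np.sum(self._rowwise_loglik(eta0)))
        sigma2 = sigma * sigma
        bhat, curv = self._find_modes(eta0, sigma2)
        tau = 1.0 / np.sqrt(-curv)
        # log integrand at each node, per group
        a = np.empty((self._nodes.size, self.n_groups))
        for k, t in enumerate(self._nodes):
            b_k = bhat + np.sqrt(2.0) * tau * t
            ll = self._group_sum(self._rowwise_loglik(eta0 + b_k[self.group_idx]))
            a[k] = ll - b_k * b_k / (2.0 * sigma2) + self._log_weights[k]
        log_li = (logsumexp(a, axis=0)
                  + np.log(np.sqrt(2.0) * tau)
                  - np.log(sigma) - _LOG_SQRT_2PI)
        return float(np.sum(log_li))

    # -- fitting -----------------------------------------------------------

    def _unpack(self, theta, fix_sigma):
        if fix_sigma is None:
            return theta[:-1], float(np.exp(theta[-1]))
        return theta, float(fix_sigma)

    def neg_loglik(self, theta, fix_sigma=None):
        beta, sigma = self._unpack(np.asarray(theta, float), fix_sigma)
        return -self.loglik(beta, sigma)

    def fit(self, beta_start, sigma_start=0.5, fix_sigma=None,
            gtol=1e-7, maxiter=500):
        """Maximize the marginal likelihood.

        Returns a dict with ``beta``, ``sigma``, ``loglik`` (including the
        binomial constant), ``cov`` (inverse numeric Hessian over the free
        parameters; the trailing parameter is log sigma when sigma is free),
        ``converged`` and ``message``.
        """
        beta_start = np.asarray(beta_start, dtype=float)
        if fix_sigma is None:
            x0 = np.r_[beta_start, np.log(max(sigma_start, 1e-3))]
            bounds = [(None, None)] * self.p + [(np.log(1e-6), np.log(50.0))]
        else:
            x0 = beta_start.copy()
            bounds = None
        res = minimize(
            self.neg_loglik, x0, args=(fix_sigma,), method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-13, "gtol": gtol},
        )
        beta, sigma = self._unpack(res.x, fix_sigma)
        hess = self._numeric_hessian(res.x, fix_sigma)
        cov, cov_ok = _safe_inverse(hess)
        converged = bool(res.success) and cov_ok
        message = res.message if isinstance(res.message, str) else str(res.message)
        if not cov_ok:
            message += "; Hessian not positive definite, pseudo-inverse used"
        return {
            "beta": np.asarray(beta, dtype=float),
            "sigma": sigma,
            "theta": res.x,
            "loglik": -res.fun + self.log_binom_const,
            "cov": cov,
            "converged": converged,
            "message": message,
            "n_iter": int(res.nit),
        }

    def _numeric_hessian(self, theta, fix_sigma, rel_step=1e-3):
        """Central-difference Hessian of the negative log likelihood."""
        theta = np.asarray(theta, dtype=float)
        m = theta.size
        h = rel_step * np.maximum(1.0, np.abs(theta))
        H = np.empty((m, m))
        f = lambda t: self.neg_loglik(t, fix_sigma)
        f0 = f(theta)
        for i in range(m):
            ei = np.zeros(m); ei[i] = h[i]
            H[i, i] = (f(theta + ei) - 2.0 * f0 + f(theta - ei)) / h[i] ** 2
        for i in range(m):
            ei = np.zeros(m); ei[i] = h[i]
            for j in range(i + 1, m):
                ej = np.zeros(m); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej)
                    - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4.0 * h[i] * h[j])
        return H


def _safe_inverse(H):
    """Invert a Hessian; fall back to the pseudo-inverse if necessary."""
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.min(eigvals) <= 0:
            return np.linalg.pinv(H), False
        return np.linalg.inv(H), True
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H), False
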