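"""Random-intercept logistic regression by Gauss–Hermite quadrature.

Model: for birth *j* in tract *i*,

    logit P(y_ij = 1) = x_ij' beta + u_i,    u_i ~ N(0, sigma_u^2).

The marginal log-likelihood integrates the tract intercept out with
Gauss–Hermite quadrature on the standardized scale u = sigma * sqrt(2) * z,
which keeps the quadrature weights independent of the parameters and
makes the gradient exact for the discretized likelihood.  The default
50 nodes are ample for the cluster sizes this package fits (the
node-doubling stability contract is asserted in the test suite); no
penalized-quasi-likelihood shortcut is taken anywhere.

Maximization is L-BFGS-B on (beta, sigma) with sigma bounded at zero,
started from the ordinary (unclustered) logistic fit.  Standard errors
come from the observed information, obtained by central finite
differences of the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp

__all__ = [
    "LogitMixedFit",
    "LinearMixedFit",
    "fit_random_intercept_logit",
    "fit_random_intercept_linear",
    "loglik_random_intercept_logit",
]


@dataclass
class LogitMixedFit:
    """Fitted random-intercept logistic model."""

    beta: np.ndarray
    sigma_u: float
    loglik: float
    cov: np.ndarray  # covariance of (beta, sigma_u)
    converged: bool
    n_obs: int
    n_clusters: int
    n_quad: int
    message: str = ""

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov)[: len(self.beta)])

    @property
    def se_sigma(self) -> float:
        return float(np.sqrt(self.cov[-1, -1]))

    @property
    def intercept_variance(self) -> float:
        return float(self.sigma_u**2)

    def wald_ci(self, index: int, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        se = self.se_beta[index]
        return self.beta[index] - z * se, self.beta[index] + z * se


def _prepare(y, X, groups):
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    groups = np.asarray(groups)
    codes, _ = _group_codes(groups)
    order = np.argsort(codes, kind="stable")
    y, X, codes = y[order], X[order], codes[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(codes)) + 1))
    return y, X, codes, starts


def _group_codes(groups):
    uniq, codes = np.unique(groups, return_inverse=True)
    return codes, uniq


def loglik_random_intercept_logit(
    params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    codes: np.ndarray,
    starts: np.ndarray,
    nodes: np.ndarray,
    logw: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Marginal log-likelihood and analytic gradient.

    ``params`` stacks the fixed effects and sigma_u last.  ``nodes``
    are sqrt(2) * Gauss–Hermite abscissae and ``logw`` the matching
    log-weights including the 1/sqrt(pi) factor.
    """
    beta, sigma = params[:-1], params[-1]
    eta = X @ beta
    B = eta[:, None] + sigma * nodes[None, :]  # (n, K)
    ll_obs = y[:, None] * B - np.logaddexp(0.0, B)
    A = np.add.reduceat(ll_obs, starts, axis=0)  # (m, K)
    Aw = A + logw[None, :]
    Li = logsumexp(Aw, axis=1)
    ll = float(np.sum(Li))
    # posterior quadrature weights per cluster
    pi = np.exp(Aw - Li[:, None])  # (m, K)
    R = y[:, None] - expit(B)  # (n, K)
    Pi_obs = pi[codes]  # (n, K)
    G = Pi_obs * R
    grad_beta = X.T @ G.sum(axis=1)
    grad_sigma = float(np.sum(G @ nodes))
    grad = np.concatenate([grad_beta, [grad_sigma]])
    return ll, grad


def fit_random_intercept_logit(
    y,
    X,
    groups,
    *,
    n_quad: int = 50,
    tol: float = 1e-13,
    max_iter: int = 1000,
    start: np.ndarray | None = None,
) -> LogitMixedFit:
    """Maximum-likelihood fit of the random-intercept logistic model.

    Parameters
    ----------
    y, X, groups
        Binary outcome, fixed-effect design matrix (including any
        intercept column) and cluster identifiers, all length-n.
    n_quad
        Gauss–Hermite nodes; doubling it should not move the estimates
        (see the stability tests).
    start
        Optional warm start ``(beta, sigma_u)``.
    """
    y, Xs, codes, starts = _prepare(y, X, groups)
    n, p = Xs.shape
    m = len(starts)
    if m < 2:
        raise ValueError("need at least 2 clusters for a random-intercept model")
    gh_x, gh_w = hermgauss(n_quad)
    nodes = np.sqrt(2.0) * gh_x
    logw = np.log(gh_w) - 0.5 * np.log(np.pi)

    if start is None:
        beta0 = _plain_logit_start(y, Xs)
        start = np.concatenate([beta0, [0.2]])
    else:
        start = np.asarray(start, dtype=float)

    def objective(params):
        ll, grad = loglik_random_intercept_logit(params, y, Xs, codes, starts, nodes, logw)
        return -ll, -grad

    bounds = [(None, None)] * p + [(0.0, None)]
    res = optimize.minimize(
        objective,
        start,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    beta_hat, sigma_hat = res.x[:-1], float(res.x[-1])
    cov = _observed_information_cov(res.x, y, Xs, codes, starts, nodes, logw)
    return LogitMixedFit(
        beta=beta_hat,
        sigma_u=sigma_hat,
        loglik=-float(res.fun),
        cov=cov,
        converged=bool(res.success),
        n_obs=n,
        n_clusters=m,
        n_quad=n_quad,
        message=str(res.message),
    )


def _plain_logit_start(y, X, max_iter: int = 25) -> np.ndarray:
    """Newton–Raphson ordinary logistic fit used as a warm start."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = mu * (1 - mu) + 1e-10
        grad = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _observed_information_cov(params, y, X, codes, starts, nodes, logw) -> np.ndarray:
    """Covariance via central differences of the analytic score."""
    q = len(params)
    H = np.zeros((q, q))
    h = 1e-5 * np.maximum(1.0, np.abs(params))
    for k in range(q):
        up, dn = params.copy(), params.copy()
        up[k] += h[k]
        dn[k] -= h[k]
        if k == q - 1 and dn[k] < 0:  # sigma stays non-negative
            dn[k] = 0.0
        _, g_up = loglik_random_intercept_logit(up, y, X, codes, starts, nodes, logw)
        _, g_dn = loglik_random_intercept_logit(dn, y, X, codes, starts, nodes, logw)
        H[k] = (g_up - g_dn) / (up[k] - dn[k])
    H = 0.5 * (H + H.T)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    # boundary or near-singular fits can yield tiny negative variances
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    np.fill_diagonal(cov, d)
    return cov


@dataclass
class LinearMixedFit:
    """Fitted random-intercept linear model (profiled REML or ML).

    ``sigma_u2`` is the between-cluster (intercept) variance and
    ``sigma_e2`` the residual variance, both in squared outcome units.
    """

    beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    loglik: float
    cov_beta: np.ndarray
    converged: bool
    n_obs: int
    n_clusters: int
    reml: bool

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))


def _lmm_profile(lam: float, y, X, codes, n_i, Sx, Sy, XtX, Xty, yty, reml: bool):
    """Profiled deviance pieces at variance ratio lam = sigma_u2/sigma_e2.

    With V_i = sigma_e2 (I + lam J), Woodbury gives
    V_i^{-1} = (I - c_i J)/sigma_e2 with c_i = lam / (1 + lam n_i),
    so all GLS quantities reduce to per-cluster sums.
    """
    c = lam / (1.0 + lam * n_i)  # (m,)
    A = XtX - (Sx * c[:, None]).T @ Sx
    b = Xty - Sx.T @ (c * Sy)
    beta = np.linalg.solve(A, b)
    quad = yty - np.sum(c * Sy**2) - beta @ b
    return beta, A, float(quad), float(np.sum(np.log1p(lam * n_i)))


def fit_random_intercept_linear(
    y, X, groups, *, reml: bool = True
) -> LinearMixedFit:
    """Random-intercept linear mixed model, y = X beta + u_group + e.

    The variance ratio is profiled out: given lam = sigma_u2/sigma_e2
    the GLS solution and residual variance are closed-form through
    per-cluster sums, leaving a one-dimensional optimization over
    log(lam).  REML (default) adds the usual log|X'V^-1 X| penalty and
    divides the residual quadratic form by n - p.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes, _ = _group_codes(np.asarray(groups))
    m = codes.max() + 1
    n, p = X.shape
    if m < 2:
        raise ValueError("need at least 2 clusters for a random-intercept model")
    n_i = np.bincount(codes).astype(float)
    Sy = np.bincount(codes, weights=y)
    Sx = np.zeros((m, p))
    for j in range(p):
        Sx[:, j] = np.bincount(codes, weights=X[:, j])
    XtX, Xty, yty = X.T @ X, X.T @ y, float(y @ y)
    dof = n - p if reml else n

    def neg_profile_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        beta, A, quad, logdet_v = _lmm_profile(
            lam, y, X, codes, n_i, Sx, Sy, XtX, Xty, yty, reml
        )
        if quad <= 0:
            return np.inf
        s2 = quad / dof
        ll = -0.5 * (dof * np.log(s2) + logdet_v + dof)
        if reml:
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            ll -= 0.5 * logdet_a
        return -ll

    grid = np.linspace(-12.0, 6.0, 37)
    vals = [neg_profile_ll(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        neg_profile_ll, bounds=(g0 - 1.5, g0 + 1.5), method="bounded",
        options={"xatol": 1e-10},
    )
    # compare against the boundary lam -> 0 (plain OLS)
    lam = float(np.exp(res.x))
    if neg_profile_ll(np.log(1e-12)) <= res.fun + 1e-10:
        lam = 0.0
    beta, A, quad, logdet_v = _lmm_profile(
        lam, y, X, codes, n_i, Sx, Sy, XtX, Xty, yty, reml
    )
    s2 = quad / dof
    cov_beta = s2 * np.linalg.inv(A)
    ll = -0.5 * (dof * np.log(s2) + logdet_v + dof)
    if reml:
        ll -= 0.5 * np.linalg.slogdet(A)[1]
    return LinearMixedFit(
        beta=beta,
        sigma_u2=lam * s2,
        sigma_e2=s2,
        loglik=float(ll),
        cov_beta=cov_beta,
        converged=bool(getattr(res, "success", True)),
        n_obs=n,
        n_clusters=int(m),
        reml=reml,
    )
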