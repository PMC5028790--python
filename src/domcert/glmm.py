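"""Generalized linear mixed models with a scalar group random intercept.

Fits log-link negative-binomial (NB2) and gamma regressions with one
Gaussian random intercept per group, using a Laplace approximation to
the marginal likelihood.  Because the random effect is scalar per group
the inner optimization is a one-dimensional Newton iteration, which
makes the whole fit deterministic and fast.

Parameterization
----------------
* NB2: Var(y) = mu + alpha * mu^2, dispersion alpha > 0 (size = 1/alpha).
* Gamma: shape k > 0, Var(y) = mu^2 / k.
* Random intercept b_g ~ N(0, sigma_b^2); as sigma_b -> 0 the marginal
  likelihood converges to the ordinary GLM likelihood (used as a
  cross-check in the tests).

Dispersion and sigma_b are estimated on the log scale.  The number of
parameters k reported for information criteria counts the fixed-effect
coefficients plus one dispersion parameter plus one random-intercept
variance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, special

_LOG_SIGMA_MIN = -8.0
_LOG_SIGMA_MAX = 3.0


def nb2_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    r = 1.0 / alpha
    return (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )


def gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> np.ndarray:
    return (
        shape * np.log(shape)
        - special.gammaln(shape)
        + (shape - 1.0) * np.log(y)
        - shape * y / mu
        - shape * np.log(mu)
    )


def _score_hess_eta(y, mu, disp, family):
    """First and second derivatives of the loglik wrt eta (log link)."""
    if family == "negbin":
        r = 1.0 / disp
        score = y - (y + r) * mu / (mu + r)
        hess = -(y + r) * r * mu / (mu + r) ** 2
    elif family == "gamma":
        score = disp * (y / mu - 1.0)
        hess = -disp * y / mu
    else:
        raise ValueError(f"unknown family {family!r}")
    return score, hess


def _loglik(y, mu, disp, family):
    if family == "negbin":
        return nb2_loglik(y, mu, disp)
    if family == "gamma":
        return gamma_loglik(y, mu, disp)
    raise ValueError(f"unknown family {family!r}")


def _laplace_group(y, eta0, disp, sigma2, family, tol=1e-10, max_iter=60):
    """Laplace-approximate log integral over one group's intercept."""
    b = 0.0
    for _ in range(max_iter):
        mu = np.exp(eta0 + b)
        score, hess = _score_hess_eta(y, mu, disp, family)
        g = float(score.sum()) - b / sigma2
        h = float(hess.sum()) - 1.0 / sigma2  # strictly negative
        step = -g / h
        # dampen huge Newton steps far from the optimum
        if abs(step) > 5.0:
            step = np.sign(step) * 5.0
        b += step
        if abs(step) < tol:
            break
    mu = np.exp(eta0 + b)
    _, hess = _score_hess_eta(y, mu, disp, family)
    h = float(hess.sum()) - 1.0 / sigma2
    q = float(_loglik(y, mu, disp, family).sum()) - 0.5 * b * b / sigma2
    # log integral ~ q(bhat) - 0.5*log(sigma2 * (-q''(bhat)))
    return q - 0.5 * np.log(sigma2 * (-h)), b


@dataclasses.dataclass
class GLMMResult:
    params: np.ndarray  # fixed-effect coefficients
    se: np.ndarray
    param_names: list[str]
    dispersion: float
    sigma_b: float
    group_effects: dict[str, float]
    loglik: float
    n: int
    k: int
    converged: bool
    family: str

    @property
    def aicc(self) -> float:
        n, k = self.n, self.k
        if n - k - 1 <= 0:
            return np.inf
        return -2.0 * self.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def coef(self, name: str) -> float:
        return float(self.params[self.param_names.index(name)])

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.params)))


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    family: str = "negbin",
    offset: np.ndarray | None = None,
    param_names: list[str] | None = None,
    start: np.ndarray | None = None,
) -> GLMMResult:
    """Fit a log-link GLMM with a single Gaussian group intercept.

    Parameters
    ----------
    y, X : response and fixed-effect design matrix (with intercept column).
    groups : group label per row (>= 2 distinct values recommended).
    family : "negbin" (NB2) or "gamma".
    offset : optional log-scale offset (e.g. log observation days).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    labels = np.asarray(groups)
    group_ids = list(dict.fromkeys(labels.tolist()))
    idx = [np.flatnonzero(labels == g) for g in group_ids]
    if param_names is None:
        param_names = [f"x{j}" for j in range(p)]

    if family == "gamma" and (y <= 0).any():
        raise ValueError("gamma family requires strictly positive outcomes")

    def unpack(theta):
        beta = theta[:p]
        disp = np.exp(np.clip(theta[p], -10, 6))
        log_sigma = np.clip(theta[p + 1], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
        sigma2 = np.exp(2.0 * log_sigma)
        return beta, disp, sigma2

    def nll(theta):
        beta, disp, sigma2 = unpack(theta)
        eta = X @ beta + offset
        total = 0.0
        for rows in idx:
            ll, _ = _laplace_group(y[rows], eta[rows], disp, sigma2, family)
            total += ll
        if not np.isfinite(total):
            return 1e12
        return -total

    if start is None:
        beta0 = np.zeros(p)
        mean_y = max(float(np.mean(y)), 1e-3)
        beta0[0] = np.log(mean_y) - float(np.mean(offset))
        disp0 = 0.5 if family == "negbin" else 1.0
        start = np.concatenate([beta0, [np.log(disp0)], [np.log(0.2)]])

    res = optimize.minimize(
        nll, start, method="BFGS",
        options={"maxiter": 500, "gtol": 1e-6},
    )
    if not res.success:
        res2 = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res2.fun < res.fun:
            res = res2
    theta = res.x
    beta, disp, sigma2 = unpack(theta)

    # observed-information SEs from a finite-difference Hessian.  The
    # sigma_b direction is often flat (few groups), making the full
    # Hessian singular; fall back to the Schur complement over the
    # fixed-effect block, then to the raw beta block.
    hess = _numeric_hessian(nll, theta)
    se = _beta_se(hess, p)

    eta = X @ beta + offset
    group_effects = {}
    for g, rows in zip(group_ids, idx):
        _, b = _laplace_group(y[rows], eta[rows], disp, sigma2, family)
        group_effects[str(g)] = float(b)

    return GLMMResult(
        params=beta,
        se=se,
        param_names=list(param_names),
        dispersion=float(disp),
        sigma_b=float(np.sqrt(sigma2)),
        group_effects=group_effects,
        loglik=float(-res.fun),
        n=n,
        k=p + 2,
        converged=bool(np.isfinite(res.fun)),
        family=family,
    )


def _beta_se(hess: np.ndarray, p: int) -> np.ndarray:
    def try_diag(cov):
        d = np.diag(cov)[:p]
        if np.all(np.isfinite(d)) and np.all(d > 0):
            return np.sqrt(d)
        return None

    try:
        out = try_diag(np.linalg.inv(hess))
        if out is not None:
            return out
    except np.linalg.LinAlgError:
        pass
    hbb = hess[:p, :p]
    hbn = hess[:p, p:]
    hnn = hess[p:, p:]
    try:
        adj = hbb - hbn @ np.linalg.pinv(hnn) @ hbn.T
        out = try_diag(np.linalg.inv(adj))
        if out is not None:
            return out
    except np.linalg.LinAlgError:
        pass
    try:
        out = try_diag(np.linalg.inv(hbb))
        if out is not None:
            return out
    except np.linalg.LinAlgError:
        pass
    return np.full(p, np.nan)


def _numeric_hessian(f, x, eps=1e-4):
    m = len(x)
    h = np.zeros((m, m))
    fx = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = steps[i]
            ej = np.zeros(m); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return h
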