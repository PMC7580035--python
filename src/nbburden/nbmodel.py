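"""Gamma-Poisson mixture (negative binomial) probability engine.

Per-sample mutation rates in a bin are treated as i.i.d. Gamma random
variables; conditional on its rate each sample contributes Poisson
counts.  Pooling ``s_d`` samples, the marginal pooled count ``y`` is
negative binomial with mean ``mu`` and overdispersion ``sigma``:

    P(y | mu, sigma) = (1 + sigma*mu)^(-1/sigma)
                       * Gamma(y + 1/sigma) / (Gamma(1/sigma) * y!)
                       * (sigma*mu / (1 + sigma*mu))^y

with Var(y) = mu * (1 + mu*sigma); sigma -> 0 recovers the Poisson.
The regression layer predicts ``log mu`` (and optionally ``log sigma``)
as a linear function of PCA-projected genomic covariates, fitted by
maximum likelihood.  Constant-sigma mode — a single overdispersion for
all bins — is the production default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # tail p-values are floored here before any log
_ETA_MAX = 700.0  # exp() overflow guard on the linear predictor
# below this sigma the Poisson limit is closer to the truth than the NB
# formula evaluated in doubles (gammaln(y + 1/sigma) - gammaln(1/sigma)
# loses ~ (1/sigma) * log(1/sigma) * eps of absolute precision)
_SIGMA_POISSON = 1e-8


@dataclass(frozen=True)
class NBParams:
    """Mean/overdispersion parameterisation of the pooled-count law."""

    mu: float
    sigma: float

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def variance(self) -> float:
        return self.mu * (1.0 + self.mu * self.sigma)


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if not np.allclose(yf, np.round(yf)):
            raise ValueError("counts must be non-negative integers")
        y = np.round(yf).astype(np.int64)
    if (y < 0).any():
        raise ValueError("counts must be non-negative integers")
    return y.astype(np.int64)


def nb_logpmf(y, mu, sigma) -> np.ndarray:
    """Log pmf of the Gamma-Poisson marginal, evaluated in log space.

    ``sigma = 0`` returns the Poisson log pmf (the exact limit).
    Broadcasts over any mix of scalar/array arguments.
    """
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if (mu <= 0).any():
        raise ValueError("mu must be > 0")
    if (sigma < 0).any():
        raise ValueError("sigma must be >= 0")
    y, mu, sigma = np.broadcast_arrays(y, mu, sigma)
    out = np.empty(y.shape, dtype=float)
    pois = sigma < _SIGMA_POISSON
    if pois.any():
        out[pois] = stats.poisson.logpmf(y[pois], mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / sigma[nb]
        sm = sigma[nb] * mu[nb]
        out[nb] = (
            special.gammaln(y[nb] + r)
            - special.gammaln(r)
            - special.gammaln(y[nb] + 1.0)
            - r * np.log1p(sm)
            + y[nb] * (np.log(sm) - np.log1p(sm))
        )
    return out if out.shape else float(out)


def nb_pmf(y, params: NBParams | None = None, *, mu=None, sigma=None):
    """Pmf of the pooled-count law; accepts NBParams or mu/sigma keywords."""
    if params is not None:
        mu, sigma = params.mu, params.sigma
    return np.exp(nb_logpmf(y, mu, sigma))


def nb_tail_pvalue(y_obs, params: NBParams | None = None, *, mu=None, sigma=None):
    """One-sided upper-tail p-value ``P(Y >= y_obs)``.

    ``y_obs = 0`` returns exactly 1.  The survival function is evaluated
    through the regularised incomplete beta function (stable for tails
    far below machine epsilon) and floored at 1e-300.
    """
    if params is not None:
        mu, sigma = params.mu, params.sigma
    y = _check_counts(y_obs)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    y, mu, sigma = np.broadcast_arrays(y, mu, sigma)
    out = np.ones(y.shape, dtype=float)
    pos = y > 0
    if pos.any():
        yp, mp, sp = y[pos], mu[pos], sigma[pos]
        vals = np.empty(yp.shape)
        pois = sp < _SIGMA_POISSON
        if pois.any():
            vals[pois] = stats.poisson.sf(yp[pois] - 1, mp[pois])
        nb = ~pois
        if nb.any():
            r = 1.0 / sp[nb]
            p_success = 1.0 / (1.0 + sp[nb] * mp[nb])
            # P(Y >= y) = I_{1-p}(y, r), regularised incomplete beta
            vals[nb] = special.betainc(yp[nb], r, 1.0 - p_success)
        out[pos] = np.maximum(vals, P_FLOOR)
    return out if out.shape else float(out)


def poisson_tail_pvalue(y_obs, lam):
    """Upper-tail ``P(Y >= y_obs)`` under Poisson(lam)."""
    y = _check_counts(y_obs)
    out = stats.poisson.sf(y - 1, lam)
    out = np.maximum(out, P_FLOOR)
    out = np.where(y == 0, 1.0, out)
    return out if np.ndim(out) else float(out)


def binomial_tail_pvalue(y_obs, region_length, p):
    """Upper-tail ``P(Y >= y_obs)`` under Binomial(region_length, p).

    ``p`` is a per-base mutation probability; the local variant of the
    baseline uses ``p = mu_region / l_region``.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p must lie in [0, 1]")
    y = _check_counts(y_obs)
    out = stats.binom.sf(y - 1, region_length, p)
    out = np.where(y == 0, 1.0, out)
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(out) else float(out)


def sample_gamma_poisson(
    params: NBParams, s_d: int, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw pooled counts through the explicit two-stage mixture.

    Each of ``s_d`` samples gets an i.i.d. rate
    ``lambda ~ Gamma(shape=1/(sigma*s_d), scale=mu*sigma)``; the pooled
    rate (a Gamma with shape 1/sigma) then drives a Poisson draw.  The
    marginal law of the output is exactly ``nb_pmf(.; mu, sigma)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if s_d < 1:
        raise ValueError("s_d must be >= 1")
    rng = np.random.default_rng(rng)
    mu, sigma = params.mu, params.sigma
    if sigma == 0:
        return rng.poisson(mu, size=n)
    shape = 1.0 / (sigma * s_d)
    scale = mu * sigma
    rates = rng.gamma(shape, scale, size=(n, s_d)).sum(axis=1)
    return rng.poisson(rates)


def fit_global_rate(n_mutations: int, usable_length: int) -> float:
    """Genome-wide constant per-base rate MLE: total mutations / bases.

    The same number serves as the Poisson rate per base and the binomial
    per-base success probability of the constant-rate baselines.
    """
    if usable_length <= 0:
        raise ValueError("usable_length must be > 0")
    if n_mutations < 0:
        raise ValueError("negative mutation count")
    return n_mutations / usable_length


def relative_error(mu_obs, mu_pred, aggregate: str = "mean") -> float:
    """Normalised prediction error ``|mu - mu_hat| / mu`` over bins.

    Bins with zero observed value are skipped with a warning (the ratio
    is undefined there).  ``aggregate`` is ``"mean"`` (default),
    ``"median"``, or ``"none"`` for the per-bin vector.
    """
    mu_obs = np.asarray(mu_obs, dtype=float)
    mu_pred = np.asarray(mu_pred, dtype=float)
    ok = mu_obs > 0
    if not ok.all():
        logger.warning("relative_error: skipping %d bins with mu_obs == 0", (~ok).sum())
    if not ok.any():
        raise ValueError("no bins with positive observed value")
    err = np.abs(mu_obs[ok] - mu_pred[ok]) / mu_obs[ok]
    if aggregate == "mean":
        return float(err.mean())
    if aggregate == "median":
        return float(np.median(err))
    if aggregate == "none":
        return err
    raise ValueError(f"unknown aggregate {aggregate!r}")


# ---------------------------------------------------------------------------
# maximum-likelihood negative binomial regression


@dataclass
class NBRegressionModel:
    """Fitted NB regression: log mu = beta . x', log sigma = alpha . x'.

    In constant-sigma mode ``alpha`` holds only the intercept, so every
    bin shares one overdispersion ``sigma = exp(alpha[0])``.
    """

    beta: np.ndarray
    alpha: np.ndarray
    constant_sigma: bool
    loglik: float
    converged: bool
    n_iter: int
    feature_names: list[str] | None = None
    bin_length: int | None = None

    @property
    def sigma(self) -> float:
        """Shared overdispersion (constant-sigma mode only)."""
        if not self.constant_sigma:
            raise ValueError("sigma varies by bin; use predict_sigma")
        return float(np.exp(self.alpha[0]))

    def predict_mu(self, X: np.ndarray) -> np.ndarray:
        eta = _design(X) @ self.beta
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    def predict_sigma(self, X: np.ndarray) -> np.ndarray:
        n = np.atleast_2d(X).shape[0]
        if self.constant_sigma:
            return np.full(n, self.sigma)
        eta = _design(X) @ self.alpha
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


def _design(X: np.ndarray) -> np.ndarray:
    """Prepend an intercept column."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(X.shape[0]), X])


def _nb_loglik(y, mu, sigma) -> float:
    r = 1.0 / sigma
    sm = sigma * mu
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            - r * np.log1p(sm)
            + y * (np.log(sm) - np.log1p(sm))
        )
    )


def _poisson_irls(D: np.ndarray, y: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Poisson-regression MLE used to initialise beta."""
    beta = np.zeros(D.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        eta = np.clip(D @ beta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        W = mu
        z = eta + (y - mu) / mu
        new, *_ = np.linalg.lstsq(D * W[:, None] ** 0.5, z * W**0.5, rcond=None)
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def fit_nb_regression(
    X: np.ndarray,
    y: np.ndarray,
    constant_sigma: bool = True,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> NBRegressionModel:
    """Maximum-likelihood NB regression of counts on covariates.

    Constant-sigma mode alternates weighted-least-squares updates of the
    mean coefficients (Fisher scoring with weights ``mu/(1+sigma*mu)``)
    with a profile-likelihood line search over ``log sigma``, starting
    from the Poisson solution and a method-of-moments overdispersion
    ``max(1e-4, (s^2 - ybar) / ybar^2)``.  The full mode additionally
    regresses ``log sigma`` on the covariates by joint quasi-Newton
    maximisation.  Convergence is declared when the relative
    log-likelihood change falls below ``tol``.
    """
    y = _check_counts(y).astype(float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("X and y have mismatched lengths")
    if not np.isfinite(X).all():
        bad = np.argwhere(~np.isfinite(X))
        raise ValueError(f"non-finite covariate at (bin, feature) {tuple(bad[0])}")
    if y.sum() <= 0:
        raise ValueError("all counts are zero; nothing to fit")

    D = _design(X)
    beta = _poisson_irls(D, y)
    ybar = y.mean()
    s2 = y.var(ddof=1) if len(y) > 1 else ybar
    sigma = max(1e-4, (s2 - ybar) / ybar**2)

    if not constant_sigma:
        return _fit_joint(D, y, beta, sigma, max_iter, tol)

    ll = _nb_loglik(y, np.exp(np.clip(D @ beta, -_ETA_MAX, _ETA_MAX)), sigma)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # profile sigma given beta
        mu = np.exp(np.clip(D @ beta, -_ETA_MAX, _ETA_MAX))
        res = optimize.minimize_scalar(
            lambda ls: -_nb_loglik(y, mu, np.exp(ls)),
            bounds=(np.log(1e-8), np.log(1e4)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        sigma = float(np.exp(res.x))
        # Fisher-scoring update of beta given sigma
        for _ in range(5):
            eta = np.clip(D @ beta, -_ETA_MAX, _ETA_MAX)
            mu = np.exp(eta)
            W = mu / (1.0 + sigma * mu)
            z = eta + (y - mu) / mu
            beta, *_ = np.linalg.lstsq(D * W[:, None] ** 0.5, z * W**0.5, rcond=None)
        mu = np.exp(np.clip(D @ beta, -_ETA_MAX, _ETA_MAX))
        new_ll = _nb_loglik(y, mu, sigma)
        if abs(new_ll - ll) <= tol * (abs(ll) + 1e-12):
            ll = new_ll
            converged = True
            break
        ll = new_ll
    if not converged:
        logger.warning("NB regression did not converge in %d iterations", max_iter)
    return NBRegressionModel(
        beta=np.asarray(beta, dtype=float),
        alpha=np.array([np.log(sigma)]),
        constant_sigma=True,
        loglik=ll,
        converged=converged,
        n_iter=it,
    )


def _fit_joint(D, y, beta0, sigma0, max_iter, tol) -> NBRegressionModel:
    """Joint fit of beta and a covariate-dependent log sigma."""
    m = D.shape[1]
    theta0 = np.concatenate([beta0, [np.log(sigma0)], np.zeros(m - 1)])

    def negll_grad(theta):
        beta, alpha = theta[:m], theta[m:]
        eta = np.clip(D @ beta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        zeta = np.clip(D @ alpha, -_ETA_MAX, _ETA_MAX)
        sigma = np.exp(zeta)
        r = 1.0 / sigma
        sm = sigma * mu
        ll = np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            - r * np.log1p(sm)
            + y * (np.log(sm) - np.log1p(sm))
        )
        dll_dmu = y / mu - (y + r) / (mu + r)
        g_beta = D.T @ (dll_dmu * mu)
        dll_dr = (
            special.digamma(y + r)
            - special.digamma(r)
            + np.log(r / (r + mu))
            + 1.0
            - (y + r) / (r + mu)
        )
        g_alpha = D.T @ (dll_dr * (-r))  # dr/dzeta = -r
        return -ll, -np.concatenate([g_beta, g_alpha])

    res = optimize.minimize(
        negll_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol},
    )
    if not res.success:
        logger.warning("joint NB regression: %s", res.message)
    return NBRegressionModel(
        beta=res.x[:m],
        alpha=res.x[m:],
        constant_sigma=False,
        loglik=-res.fun,
        converged=bool(res.success),
        n_iter=int(res.nit),
    )
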