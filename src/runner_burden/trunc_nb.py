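"""Left-truncated negative-binomial regression.

The count model at the heart of the burden test.  A gene's weighted
rare-allele count ``y`` is modelled as negative binomial with gene-specific
mean ``mu = exp(x . beta)`` and a shared dispersion ``theta``
(``Var[y] = mu + mu**2 / theta``).  Because small samples inflate the number
of genes with zero or very few alleles, the distribution is renormalized on
the support ``{t+1, t+2, ...}`` for a truncation point ``t >= 0``
(``t = -1`` means no truncation).

The module provides the probability mass functions, the analytic
log-likelihood gradient, a quasi-Newton maximum-likelihood fitter, the
saturated (per-observation) means, signed deviance residuals, and the
standardization of residuals into one-sided normal p-values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .exceptions import (
    ConvergenceWarning,
    DomainError,
    IdentifiabilityError,
    NumericalError,
    SupportError,
)

_MU_EPS = 1e-8  # lower bracket / boundary sentinel for saturated means


# ---------------------------------------------------------------------------
# Probability mass functions
# ---------------------------------------------------------------------------

def _validate_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.all(np.isfinite(y)):
        raise DomainError("counts must be finite")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise DomainError("counts must be non-negative integers")
    return y.astype(np.int64)


def nb_logpmf(y, mu, theta):
    """Log PMF of NB(mu, theta) computed via log-gamma terms."""
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    return (
        special.gammaln(y + theta)
        - special.gammaln(theta)
        - special.gammaln(y + 1.0)
        + y * (np.log(mu) - np.log(mu + theta))
        + theta * (np.log(theta) - np.log(mu + theta))
    )


def nb_pmf(y, mu, theta):
    """NB probability mass ``f(y | mu, theta)``.

    Parameters
    ----------
    y : int or array of int
        Non-negative counts.
    mu : float
        Mean, > 0.
    theta : float
        Dispersion, > 0; ``theta -> inf`` recovers the Poisson.
    """
    y = _validate_counts(y)
    if not (np.all(np.asarray(mu) > 0) and theta > 0):
        raise DomainError("mu and theta must be positive")
    return np.exp(nb_logpmf(y, mu, theta))


def _log_trunc_denom(mu, theta, t: int):
    """``log(1 - F(t))`` via the NB log-survival function.

    Stable even when essentially all mass sits at or below ``t`` (where the
    naive ``log1p(-exp(logsumexp(...)))`` complement loses every digit); an
    underflow of the survival function itself raises.
    """
    mu = np.asarray(mu, dtype=np.float64)
    with np.errstate(divide="ignore"):
        lsf = stats.nbinom.logsf(t, theta, theta / (theta + mu))
    if np.any(~np.isfinite(lsf)):
        raise NumericalError(
            "truncated-NB denominator underflow: essentially all probability "
            "mass lies at or below the truncation point"
        )
    return lsf


def tnb_logpmf(y, mu, theta, t: int):
    """Log PMF of the left-truncated NB on support {t+1, t+2, ...}."""
    y = np.atleast_1d(np.asarray(y))
    mu = np.broadcast_to(np.asarray(mu, dtype=np.float64), y.shape).copy()
    lf = nb_logpmf(y, mu, theta)
    if t >= 0:
        lf = lf - _log_trunc_denom(mu.ravel(), theta, t).reshape(y.shape)
    return lf


def tnb_pmf(y, mu, theta, t: int):
    """Truncated-NB mass ``g(y | mu, theta, t) = f(y) / (1 - F(t))``.

    Raises
    ------
    SupportError
        If any ``y <= t`` (outside the truncated support).
    NumericalError
        If the renormalizing denominator underflows.
    """
    y = _validate_counts(y)
    if not (np.all(np.asarray(mu) > 0) and theta > 0):
        raise DomainError("mu and theta must be positive")
    if np.any(y <= t):
        raise SupportError(f"count outside truncated support (y <= t = {t})")
    scalar = y.ndim == 0
    out = np.exp(tnb_logpmf(y, mu, theta, t))
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Log-likelihood and analytic gradient
# ---------------------------------------------------------------------------

def tnb_loglik_and_grad(beta, log_theta, X, y, t: int):
    """Total log-likelihood and its gradient over ``(beta, log theta)``.

    ``mu_i = exp(X_i . beta)``.  All rows must satisfy ``y_i > t``.

    Returns
    -------
    (loglik, grad) : float, ndarray of shape (len(beta) + 1,)
        The gradient's last entry is with respect to ``log theta``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise DomainError("no observations supplied")
    if np.any(y <= t):
        raise SupportError("all observations must satisfy y > t")
    beta = np.asarray(beta, dtype=np.float64)
    theta = float(np.exp(log_theta))

    eta = X @ beta
    mu = np.exp(eta)

    # untruncated score contributions
    d_eta = y - mu * (y + theta) / (mu + theta)
    d_theta = (
        special.digamma(y + theta)
        - special.digamma(theta)
        + np.log(theta) + 1.0
        - np.log(mu + theta)
        - (y + theta) / (mu + theta)
    )
    ll = np.sum(nb_logpmf(y, mu, theta))

    if t >= 0:
        j = np.arange(t + 1, dtype=np.float64)[:, None]  # (t+1, 1)
        logf_j = nb_logpmf(j, mu[None, :], theta)
        lsf = _log_trunc_denom(mu, theta, t)
        denom = np.exp(lsf)
        if np.any(denom < 1e-290):
            # gradient terms need the linear-scale denominator
            raise NumericalError("truncation mass ~ 1; gradient undefined")
        f_j = np.exp(logf_j)
        s_eta_j = j - mu[None, :] * (j + theta) / (mu[None, :] + theta)
        s_theta_j = (
            special.digamma(j + theta)
            - special.digamma(theta)
            + np.log(theta) + 1.0
            - np.log(mu[None, :] + theta)
            - (j + theta) / (mu[None, :] + theta)
        )
        ll -= np.sum(lsf)
        d_eta = d_eta + np.sum(f_j * s_eta_j, axis=0) / denom
        d_theta = d_theta + np.sum(f_j * s_theta_j, axis=0) / denom

    grad = np.concatenate([X.T @ d_eta, [theta * np.sum(d_theta)]])
    return float(ll), grad


# ---------------------------------------------------------------------------
# Model container and fitting
# ---------------------------------------------------------------------------

@dataclass
class TNBModel:
    """Fitted truncated-NB regression.

    ``beta`` is on the raw predictor scale (intercept first); ``beta_std``
    on the internally standardized scale actually optimized.  ``t = -1``
    denotes the untruncated model.
    """

    beta: np.ndarray
    theta: float
    t: int
    converged: bool
    loglik: float
    n_fit: int
    vcov: np.ndarray | None = None
    beta_std: np.ndarray | None = None
    col_mean: np.ndarray | None = None
    col_scale: np.ndarray | None = None
    b: float | None = None  # score bin length used to build the counts
    n_iter: int = 0

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.theta <= 0:
            raise DomainError("theta must be positive")

    def predict_mu(self, X) -> np.ndarray:
        """Fitted means ``exp(beta0 + sum_k beta_k x_k)`` for raw predictors."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] == self.beta.size - 1:  # without intercept column
            X = np.column_stack([np.ones(X.shape[0]), X])
        return np.exp(X @ self.beta)

    def to_json(self) -> str:
        doc = {
            "beta": self.beta.tolist(),
            "theta": self.theta,
            "t": self.t,
            "b": self.b,
            "converged": self.converged,
            "loglik": self.loglik,
            "n_fit": self.n_fit,
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TNBModel":
        doc = json.loads(text)
        return cls(
            beta=np.asarray(doc["beta"]), theta=doc["theta"], t=doc["t"],
            converged=doc["converged"], loglik=doc["loglik"],
            n_fit=doc["n_fit"], b=doc.get("b"),
        )


def predict_mu(model: TNBModel, X) -> np.ndarray:
    """Functional alias for :meth:`TNBModel.predict_mu`."""
    return model.predict_mu(X)


def _check_design(X: np.ndarray) -> None:
    sd = X.std(axis=0)
    if np.any(sd[1:] == 0):
        bad = list(np.where(sd[1:] == 0)[0] + 1)
        raise IdentifiabilityError(f"zero-variance predictor column(s): {bad}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise IdentifiabilityError("collinear design matrix")


def _init_params(Z: np.ndarray, y: np.ndarray, t: int) -> np.ndarray:
    """Poisson log-linear start for beta; method-of-moments for log theta."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, Z, family=sm.families.Poisson()).fit()
    beta0 = np.asarray(pois.params)
    mu0 = np.clip(pois.mu, 1e-6, None)
    resid_var = np.mean((y - mu0) ** 2 - mu0)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta0 = np.mean(mu0**2) / resid_var if resid_var > 0 else 100.0
    theta0 = float(np.clip(theta0, 0.05, 1e4))
    return np.concatenate([beta0, [np.log(theta0)]])


def _newton_polish(objective, x, f, gtol, max_steps: int = 8):
    """Newton refinement of a quasi-Newton optimum.

    Uses central finite differences of the analytic gradient for the
    Hessian; each step is accepted only if it lowers the objective.  Drives
    the gradient max-norm well below the BFGS line-search floor.
    """
    h = 1e-6
    k = x.size
    _, g = objective(x)
    gnorm = np.max(np.abs(g))
    for _ in range(max_steps):
        if gnorm < gtol / 100.0:
            break
        H = np.empty((k, k))
        for i in range(k):
            up, dn = x.copy(), x.copy()
            up[i] += h
            dn[i] -= h
            H[i] = (objective(up)[1] - objective(dn)[1]) / (2 * h)
        H = (H + H.T) / 2
        try:
            step = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            break
        accepted = False
        for scale in (1.0, 0.5, 0.25, 0.1):
            cand = x + scale * step
            fc, gc = objective(cand)
            # near the optimum the objective sits at the float-precision
            # floor; progress is judged by the gradient norm instead
            tol = 1e-8 * max(1.0, abs(f))  # objective noise floor near optimum
            if np.isfinite(fc) and fc <= f + tol and np.max(np.abs(gc)) < gnorm:
                x, f, g, gnorm = cand, min(f, fc), gc, np.max(np.abs(gc))
                accepted = True
                break
        if not accepted:
            break
    return x, f


def fit_tnb_regression(
    X,
    y,
    t: int,
    *,
    init: Sequence[float] | None = None,
    theta_fixed: float | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
    add_intercept: bool = True,
) -> TNBModel:
    """Maximum-likelihood fit of the truncated-NB regression.

    Optimizes over ``(beta, log theta)`` by BFGS with the analytic gradient,
    starting from a Poisson log-linear fit and a method-of-moments dispersion
    estimate.  Predictor columns are standardized internally; reported
    coefficients are mapped back to the raw scale.

    Parameters
    ----------
    X : (n, p) array
        Raw predictor matrix, without intercept unless
        ``add_intercept=False``.
    y : (n,) array of int
        Counts; every row must satisfy ``y > t``.
    t : int
        Truncation point (>= -1).
    theta_fixed : float, optional
        Fix the dispersion (e.g. a huge value yields a truncated-Poisson
        regression) and optimize beta only.
    init : sequence, optional
        Raw-scale starting values ``(beta..., log theta)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = _validate_counts(y)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
    n, p = X.shape
    if np.any(y <= t):
        raise SupportError("fit requires all counts strictly above t")
    if n < 10 * p:
        raise DomainError(
            f"need at least 10x more rows ({n}) than coefficients ({p})"
        )
    _check_design(X)

    # standardize non-intercept columns for optimizer conditioning
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    mean[0], scale[0] = 0.0, 1.0
    Z = (X - mean) / scale

    yf = y.astype(np.float64)
    if init is not None:
        init = np.asarray(init, dtype=np.float64)
        b_raw, lth = init[:p], init[p]
        b_std = b_raw * scale
        b_std[0] = b_raw[0] + np.sum(b_raw[1:] * mean[1:])
        x0 = np.concatenate([b_std, [lth]])
    else:
        x0 = _init_params(Z, yf, t)

    if theta_fixed is not None:
        lth_fix = np.log(theta_fixed)

        def objective(params):
            # wild line-search steps can push all mass below t; report a
            # huge objective so the search backtracks
            try:
                ll, g = tnb_loglik_and_grad(params, lth_fix, Z, yf, t)
            except NumericalError:
                return 1e12, np.zeros(p)
            return -ll / n, -g[:p] / n

        x0 = x0[:p]
    else:
        def objective(params):
            try:
                ll, g = tnb_loglik_and_grad(params[:p], params[p], Z, yf, t)
            except NumericalError:
                return 1e12, np.zeros(p + 1)
            return -ll / n, -g / n

    res = optimize.minimize(
        objective, x0, jac=True, method="BFGS",
        options={"gtol": gtol / 10.0, "maxiter": maxiter},
    )
    xopt, fopt = _newton_polish(objective, res.x, res.fun, gtol)
    res.x, res.fun = xopt, fopt
    _, gfin = objective(xopt)
    gmax = float(np.max(np.abs(gfin)))
    converged = bool(gmax < gtol)
    if not converged:
        warnings.warn(
            f"truncated-NB fit stopped without convergence (|grad|max={gmax:.3g})",
            ConvergenceWarning,
        )

    params = res.x
    if theta_fixed is not None:
        beta_std = params
        log_theta = np.log(theta_fixed)
    else:
        beta_std = params[:p]
        log_theta = params[p]
    theta = float(np.exp(log_theta))

    beta = beta_std / scale
    beta[0] = beta_std[0] - np.sum(beta_std[1:] * mean[1:] / scale[1:])

    vcov = None
    if theta_fixed is None:
        vcov = _observed_info_vcov(params, Z, yf, t, mean, scale)

    ll_total = -res.fun * n
    return TNBModel(
        beta=beta, theta=theta, t=t, converged=converged,
        loglik=float(ll_total), n_fit=n, vcov=vcov, beta_std=beta_std,
        col_mean=mean, col_scale=scale, n_iter=int(res.nit),
    )


def _observed_info_vcov(params, Z, y, t, mean, scale):
    """Covariance of (raw beta, log theta) from the observed information.

    The Hessian is formed by central differences of the analytic gradient on
    the standardized scale and mapped back through the (linear)
    standardization Jacobian.
    """
    p = Z.shape[1]
    k = params.size
    H = np.zeros((k, k))
    h = 1e-5
    for i in range(k):
        up, dn = params.copy(), params.copy()
        up[i] += h
        dn[i] -= h
        _, gu = tnb_loglik_and_grad(up[:p], up[p], Z, y, t)
        _, gd = tnb_loglik_and_grad(dn[:p], dn[p], Z, y, t)
        H[i] = (gu - gd) / (2 * h)
    H = (H + H.T) / 2
    try:
        cov_std = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    # beta_raw = A @ beta_std with A lower-triangular in the intercept row
    A = np.eye(k)
    A[0, 1:p] = -mean[1:] / scale[1:]
    for i in range(1, p):
        A[i, i] = 1.0 / scale[i]
    return A @ cov_std @ A.T


# ---------------------------------------------------------------------------
# Saturated means and deviance residuals
# ---------------------------------------------------------------------------

def saturated_mu(y: int, theta: float, t: int) -> float:
    """Mean maximizing the (truncated) NB likelihood of a single count.

    For the untruncated model this is ``y`` itself.  Under truncation the
    optimum is found by bounded 1-D minimization on
    ``[1e-8, 10 * max(y, 1)]``; a solution at the lower bound is returned as
    the boundary sentinel ``1e-8`` (the likelihood of small counts can be
    monotone increasing toward ``mu -> 0``).
    """
    y = int(y)
    if y <= t:
        raise SupportError(f"y={y} outside support for t={t}")
    if theta <= 0:
        raise DomainError("theta must be positive")
    if t < 0:
        return float(max(y, _MU_EPS))
    hi = 10.0 * max(y, 1)

    def nll(mu):
        return -float(tnb_logpmf(np.array([y]), mu, theta, t)[0])

    res = optimize.minimize_scalar(
        nll, bounds=(_MU_EPS, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    mu_star = float(res.x)
    if mu_star <= _MU_EPS * 10:
        return _MU_EPS
    return mu_star


def saturated_loglik_table(y_values, theta: float, t: int) -> dict[int, float]:
    """Saturated log-likelihood for each distinct count (cached per fit)."""
    out = {}
    for yy in np.unique(np.asarray(y_values, dtype=np.int64)):
        mu_s = saturated_mu(int(yy), theta, t)
        out[int(yy)] = float(tnb_logpmf(np.array([yy]), mu_s, theta, t)[0])
    return out


def deviance_residual(y, mu_hat, theta, t, *, _sat_table=None):
    """Signed deviance residuals under the truncated-NB model.

    ``e = sign(y - mu_hat) * sqrt(2 |l(y | mu*, theta, t) - l(y | mu_hat,
    theta, t)|)`` with ``mu*`` the saturated mean.
    """
    y = _validate_counts(np.atleast_1d(y))
    mu_hat = np.broadcast_to(np.asarray(mu_hat, dtype=np.float64), y.shape)
    if np.any(y <= t):
        raise SupportError("deviance residual defined only for y > t")
    table = _sat_table or saturated_loglik_table(y, theta, t)
    l_sat = np.array([table[int(v)] for v in y])
    l_fit = tnb_logpmf(y, mu_hat, theta, t)
    e = np.sign(y - mu_hat) * np.sqrt(2.0 * np.abs(l_sat - l_fit))
    return e if e.shape != (1,) else float(e[0])


def standardize_and_pvalue(e_background, e_all):
    """Standardize residuals and convert to one-sided normal p-values.

    The location and scale are the empirical mean and standard deviation of
    the background (null-model) residuals; they are applied to every gene.
    ``p = 1 - Phi(e_std)`` — upper one-sided, so only excess burden is small.

    Returns
    -------
    (e_std, p) : ndarrays aligned with ``e_all``.
    """
    e_background = np.asarray(e_background, dtype=np.float64)
    e_all = np.asarray(e_all, dtype=np.float64)
    if e_background.size < 2:
        raise DomainError("need at least 2 background residuals")
    m = e_background.mean()
    s = e_background.std(ddof=1)
    if s <= 0 or not np.isfinite(s):
        raise DomainError("background residuals have zero variance")
    e_std = (e_all - m) / s
    p = stats.norm.sf(e_std)
    return e_std, p
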