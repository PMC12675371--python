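"""Parametric accelerated failure time (AFT) models for right-censored data.

The central model is the log-normal AFT

    log T = X beta + sigma W,   W ~ N(0, 1),

fit by maximum likelihood over (beta, log sigma).  For an event at t the
contribution is log phi(z) - log(sigma t) with z = (log t - x beta) / sigma;
a right-censored observation contributes log(1 - Phi(z)).  Covariate effects
are reported as hazard ratios HR = exp(-beta / sigma): because higher x beta
stretches survival time, a negative coefficient accelerates failure and
yields HR > 1.  Confidence intervals for the HR come from the delta method
applied to g = -beta / sigma on the (beta, sigma) covariance block.

Weibull and log-logistic AFT variants (Gumbel / logistic error on log-time)
are provided for AIC-based family comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, log_expit
from statsmodels.tools.numdiff import approx_hess

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # normal 97.5% quantile for Wald intervals

FAMILIES = ("lognormal", "weibull", "loglogistic")


def _error_logpdf(z, family):
    if family == "lognormal":
        return stats.norm.logpdf(z)
    if family == "weibull":  # Gumbel (minimum) error on log-time
        return z - np.exp(z)
    if family == "loglogistic":  # logistic error on log-time
        return z - 2.0 * np.logaddexp(0.0, z)
    raise ConfigurationError(f"unknown AFT family {family!r}")


def _error_logsf(z, family):
    if family == "lognormal":
        return stats.norm.logsf(z)
    if family == "weibull":
        return -np.exp(z)
    if family == "loglogistic":
        return log_expit(-z)
    raise ConfigurationError(f"unknown AFT family {family!r}")


def _error_dlogpdf(z, family):
    if family == "lognormal":
        return -z
    if family == "weibull":
        return 1.0 - np.exp(z)
    if family == "loglogistic":
        return 1.0 - 2.0 * expit(z)
    raise ConfigurationError(f"unknown AFT family {family!r}")


def _error_dlogsf(z, family):
    if family == "lognormal":
        # -phi(z)/S(z), computed in the log domain to survive deep tails
        return -np.exp(stats.norm.logpdf(z) - stats.norm.logsf(z))
    if family == "weibull":
        return -np.exp(z)
    if family == "loglogistic":
        return -expit(z)
    raise ConfigurationError(f"unknown AFT family {family!r}")


def aft_loglik(beta, sigma, X, time, event, family: str = "lognormal") -> float:
    """Censored AFT log-likelihood at (beta, sigma).

    Events contribute ``log f0(z) - log(sigma t)``; right-censored rows
    contribute ``log S0(z)``, with ``z = (log t - x beta) / sigma`` and
    (f0, S0) the standard error density/survival of the chosen family.
    """
    if sigma <= 0:
        raise ConfigurationError("sigma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time <= 0).any():
        raise ValidationError("AFT likelihood requires positive times")
    z = (np.log(time) - X @ np.asarray(beta, float)) / sigma
    ev = event == 1
    return float(
        np.sum(_error_logpdf(z[ev], family) - np.log(sigma * time[ev]))
        + np.sum(_error_logsf(z[~ev], family))
    )


def _loglik_and_grad(theta, X, logt, event, family):
    """Log-likelihood and gradient in the (beta, log sigma) parameterization."""
    beta, logsig = theta[:-1], theta[-1]
    sigma = np.exp(logsig)
    z = (logt - X @ beta) / sigma
    ev = event == 1
    ll = (
        np.sum(_error_logpdf(z[ev], family) - logsig - logt[ev])
        + np.sum(_error_logsf(z[~ev], family))
    )
    psi = np.where(ev, _error_dlogpdf(z, family), _error_dlogsf(z, family))
    # d z / d beta_j = -x_j / sigma;  d z / d logsig = -z; events add -1 from -logsig
    grad_beta = -(psi / sigma) @ X
    grad_logsig = np.sum(psi * (-z)) - ev.sum()
    return ll, np.r_[grad_beta, grad_logsig]


@dataclass
class AFTFit:
    """Fitted AFT model with Wald inference in Table-of-estimates form.

    ``params`` has one row per parameter (intercept, covariates, scale) with
    columns estimate, se, ci_lower, ci_upper, chi_square, p, hr.  The
    covariance is reported on the (beta, sigma) scale.
    """

    family: str
    terms: list[str]
    beta: np.ndarray  # includes the intercept as the first entry
    sigma: float
    loglik: float
    aic: float
    covariance: np.ndarray
    params: pd.DataFrame
    converged: bool
    n_obs: int
    n_events: int


def hazard_ratio(beta: float | np.ndarray, scale: float) -> float | np.ndarray:
    """Log-normal AFT hazard ratio HR = exp(-beta / scale) for one covariate."""
    if np.any(np.asarray(scale) <= 0):
        raise ConfigurationError("scale must be positive")
    return np.exp(-np.asarray(beta, dtype=float) / scale)


def fit_aft(
    X,
    time,
    event,
    family: str = "lognormal",
    add_intercept: bool = True,
    terms: list[str] | None = None,
    max_iter: int = 500,
) -> AFTFit:
    """Maximum-likelihood AFT fit with Wald standard errors.

    Optimizes over (beta, log sigma) so the scale stays positive, starting
    from beta = 0 (intercept at the mean log event time) and sigma = SD of
    log event times.  The covariance comes from the inverse observed
    information (numeric Hessian), transformed to the (beta, sigma) scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time <= 0).any():
        raise ValidationError("AFT model requires positive times")
    n, p = X.shape
    if event.sum() < p + 2:
        raise ValidationError(
            f"need at least p + 2 = {p + 2} events to fit {p} covariates"
        )
    if terms is None:
        terms = [f"x{j}" for j in range(p)]
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        terms = ["Intercept"] + list(terms)
    logt = np.log(time)
    ev = event == 1

    theta0 = np.zeros(X.shape[1] + 1)
    if add_intercept:
        theta0[0] = logt[ev].mean()
    sd0 = logt[ev].std(ddof=1)
    theta0[-1] = np.log(sd0 if sd0 > 0 else 1.0)

    def negloglik(theta):
        ll, g = _loglik_and_grad(theta, X, logt, event, family)
        return -ll, -g

    res = minimize(
        negloglik,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-9},
    )
    # line searches can stall from rounding near the optimum; accept the fit
    # when the score is numerically flat there
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) or grad_norm < 1e-4 * (1.0 + abs(res.fun))
    if not converged:
        warnings.warn(f"AFT ({family}) fit did not converge: {res.message}")
    theta = res.x
    beta, sigma = theta[:-1], float(np.exp(theta[-1]))
    loglik = -float(res.fun)
    n_params = theta.size
    aic = 2.0 * n_params - 2.0 * loglik

    hess = approx_hess(theta, lambda th: _loglik_and_grad(th, X, logt, event, family)[0])
    info = -hess
    try:
        cov_logsig = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        # e.g. a constant-zero covariate carries no information; report the
        # estimable part and flag the degenerate directions with zero SE
        warnings.warn("observed information is singular; using a pseudo-inverse")
        cov_logsig = np.linalg.pinv(info)
    # transform (beta, log sigma) covariance to (beta, sigma)
    jac = np.eye(n_params)
    jac[-1, -1] = sigma
    cov = jac @ cov_logsig @ jac.T

    est = np.r_[beta, sigma]
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(se > 0, (est / se) ** 2, np.nan)
    pvals = stats.chi2.sf(chi2, df=1)
    names = terms + ["Scale"]
    hr = np.full(n_params, np.nan)
    cov_idx = range(1 if add_intercept else 0, n_params - 1)
    for j in cov_idx:
        hr[j] = hazard_ratio(beta[j], sigma)
    table = pd.DataFrame(
        {
            "parameter": names,
            "estimate": est,
            "se": se,
            "ci_lower": est - Z95 * se,
            "ci_upper": est + Z95 * se,
            "chi_square": chi2,
            "p": pvals,
            "hr": hr,
        }
    )
    # scale p/chi2 are about sigma = 0, which is not a meaningful null
    table.loc[table["parameter"] == "Scale", ["chi_square", "p"]] = np.nan
    return AFTFit(
        family=family,
        terms=terms,
        beta=beta,
        sigma=sigma,
        loglik=loglik,
        aic=aic,
        covariance=cov,
        params=table,
        converged=converged,
        n_obs=n,
        n_events=int(event.sum()),
    )


def fit_aft_lognormal(X, time, event, **kwargs) -> AFTFit:
    """Log-normal AFT maximum-likelihood fit (see :func:`fit_aft`)."""
    return fit_aft(X, time, event, family="lognormal", **kwargs)


def hazard_ratios(fit: AFTFit) -> pd.DataFrame:
    """Per-covariate hazard ratios with delta-method 95% intervals.

    For g = -beta_j / sigma the gradient is (-1/sigma, beta_j/sigma^2); its
    variance uses the (beta_j, sigma) covariance block and the interval is
    exponentiated.
    """
    sigma = fit.sigma
    sig_idx = len(fit.beta)  # scale position in the covariance
    rows = []
    start = 1 if fit.terms and fit.terms[0] == "Intercept" else 0
    for j in range(start, len(fit.beta)):
        b = fit.beta[j]
        g = -b / sigma
        grad = np.array([-1.0 / sigma, b / sigma**2])
        block = fit.covariance[np.ix_([j, sig_idx], [j, sig_idx])]
        var_g = float(grad @ block @ grad)
        sd_g = np.sqrt(max(var_g, 0.0))
        rows.append(
            {
                "term": fit.terms[j],
                "hr": np.exp(g),
                "hr_ci_lower": np.exp(g - Z95 * sd_g),
                "hr_ci_upper": np.exp(g + Z95 * sd_g),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FamilyComparison:
    """AICs of candidate AFT families and the minimum-AIC choice."""

    table: pd.DataFrame  # family, loglik, aic, converged
    chosen: str
    fits: dict[str, AFTFit]


def aic_family_select(X, time, event, families=FAMILIES, **kwargs) -> FamilyComparison:
    """Fit each candidate family and choose the one with minimal AIC.

    Families that fail to converge are excluded from the choice (warned);
    if none converge the minimum over all fits is used.
    """
    rows, fits = [], {}
    for family in families:
        fit = fit_aft(X, time, event, family=family, **kwargs)
        fits[family] = fit
        rows.append(
            {
                "family": family,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "converged": fit.converged,
            }
        )
        if not fit.converged:
            warnings.warn(f"family {family} excluded from AIC choice (no convergence)")
    table = pd.DataFrame(rows)
    usable = table[table["converged"]] if table["converged"].any() else table
    chosen = usable.loc[usable["aic"].idxmin(), "family"]
    return FamilyComparison(table=table, chosen=str(chosen), fits=fits)
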