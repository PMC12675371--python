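"""Penalized Cox proportional-hazards feature selectors.

Ridge, lasso and elastic-net Cox models minimize

    L(beta) = -l(beta) + lambda * [alpha * ||beta||_1 + (1 - alpha) * ||beta||_2^2]

where ``l`` is the Breslow-tie Cox partial log-likelihood (ridge: alpha = 0,
lasso: alpha = 1).  The smooth part is handled with L-BFGS when there is no
L1 term and with a monotone proximal-gradient (ISTA with backtracking)
otherwise, so lasso/elastic coefficients are exactly zero when shrunk out.
Selection across cross-validation folds uses the rank-sum rule: genes are
ranked per fold by |beta| and the genes with the smallest rank sums win.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

_KINDS = ("ridge", "lasso", "elastic")


def _sorted_views(X, time, event):
    """Sort descending by time and locate tie-block ends (Breslow risk sets)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(-time, kind="stable")
    t = time[order]
    # ends[i]: last index sharing i's time -> Breslow risk set of i = rows 0..ends[i]
    is_last = np.r_[t[1:] != t[:-1], True]
    last_idx = np.flatnonzero(is_last)
    ends = last_idx[np.searchsorted(last_idx, np.arange(t.size), side="left")]
    return X[order], t, event[order], ends


def cox_partial_loglik(beta, X, time, event) -> float:
    """Breslow-tie Cox partial log-likelihood l(beta)."""
    value, _ = _cox_loglik_grad(beta, X, time, event, want_grad=False)
    return value


def cox_partial_loglik_grad(beta, X, time, event) -> np.ndarray:
    """Gradient of the Breslow partial log-likelihood with respect to beta."""
    _, grad = _cox_loglik_grad(beta, X, time, event, want_grad=True)
    return grad


def _cox_loglik_grad(beta, X, time, event, want_grad=True):
    beta = np.asarray(beta, dtype=float)
    Xs, ts, es, ends = _sorted_views(X, time, event)
    if es.sum() == 0:
        raise ValidationError("Cox partial likelihood undefined without events")
    eta = Xs @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    cum_w = np.cumsum(w)
    log_risk = np.log(cum_w[ends]) + shift  # log sum_{t_j >= t_i} e^{eta_j}
    ev = es == 1
    loglik = float(np.sum(eta[ev] - log_risk[ev]))
    if not want_grad:
        return loglik, None
    cum_wx = np.cumsum(w[:, None] * Xs, axis=0)
    mean_x = cum_wx[ends] / cum_w[ends][:, None]
    grad = (Xs[ev] - mean_x[ev]).sum(axis=0)
    return loglik, grad


@dataclass
class PenalizedCoxFit:
    """Result of a penalized Cox fit."""

    beta: np.ndarray
    kind: str
    lam: float
    alpha: float
    converged: bool
    loglik: float
    objective: float
    n_iter: int
    objective_path: np.ndarray = field(repr=False, default=None)


def _objective(beta, X, time, event, lam, alpha):
    loglik = cox_partial_loglik(beta, X, time, event)
    pen = lam * (alpha * np.abs(beta).sum() + (1 - alpha) * np.square(beta).sum())
    return -loglik + pen


def fit_penalized_cox(
    X,
    time,
    event,
    kind: str = "elastic",
    lam: float = 0.1,
    alpha: float = 0.5,
    max_iter: int = 5000,
    tol: float = 1e-7,
) -> PenalizedCoxFit:
    """Fit a ridge/lasso/elastic-net Cox model at a fixed penalty strength.

    ``X`` is expected standardized.  ``kind`` fixes the L1 fraction: ridge
    -> alpha = 0, lasso -> alpha = 1, elastic uses the given ``alpha``.
    Convergence is declared when the objective changes by less than ``tol``
    (relative to its magnitude); non-convergence returns a flagged fit.
    """
    if kind not in _KINDS:
        raise ConfigurationError(f"kind must be one of {_KINDS}")
    if lam < 0 or not 0 <= alpha <= 1:
        raise ConfigurationError("require lam >= 0 and alpha in [0, 1]")
    if kind == "ridge":
        alpha = 0.0
    elif kind == "lasso":
        alpha = 1.0
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    l1 = lam * alpha
    l2 = lam * (1 - alpha)

    def smooth_val_grad(beta):
        loglik, grad = _cox_loglik_grad(beta, X, time, event)
        return (-loglik + l2 * np.square(beta).sum(), -grad + 2 * l2 * beta)

    if l1 == 0.0:
        res = minimize(
            smooth_val_grad,
            np.zeros(p),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9},
        )
        beta = res.x
        obj = _objective(beta, X, time, event, lam, alpha)
        fit = PenalizedCoxFit(
            beta=beta,
            kind=kind,
            lam=lam,
            alpha=alpha,
            converged=bool(res.success),
            loglik=cox_partial_loglik(beta, X, time, event),
            objective=obj,
            n_iter=int(res.nit),
            objective_path=np.array([obj]),
        )
        if not res.success:
            warnings.warn(f"penalized Cox ({kind}) did not converge: {res.message}")
        return fit

    # proximal gradient (ISTA with backtracking): monotone in the objective
    beta = np.zeros(p)
    step = 1.0
    f_val, f_grad = smooth_val_grad(beta)
    obj = f_val + l1 * np.abs(beta).sum()
    path = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        while True:
            cand = beta - step * f_grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * l1, 0.0)
            diff = cand - beta
            f_cand, g_cand = smooth_val_grad(cand)
            # backtracking majorization check
            if f_cand <= f_val + f_grad @ diff + (diff @ diff) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-14:
                break
        new_obj = f_cand + l1 * np.abs(cand).sum()
        if new_obj > obj + 1e-12:  # safeguard; should not trigger
            break
        beta, f_val, f_grad = cand, f_cand, g_cand
        path.append(new_obj)
        if abs(obj - new_obj) <= tol * (1.0 + abs(new_obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
        step *= 1.5  # allow the step to grow back
    if not converged:
        warnings.warn(f"penalized Cox ({kind}) did not converge in {it} iterations")
    return PenalizedCoxFit(
        beta=beta,
        kind=kind,
        lam=lam,
        alpha=alpha,
        converged=converged,
        loglik=cox_partial_loglik(beta, X, time, event),
        objective=obj,
        n_iter=it,
        objective_path=np.asarray(path),
    )


def lambda_max(X, time, event, alpha: float = 1.0) -> float:
    """Smallest penalty that keeps all coefficients at zero (L1 part > 0)."""
    grad0 = cox_partial_loglik_grad(np.zeros(np.atleast_2d(X).shape[1]), X, time, event)
    if alpha <= 0:
        raise ConfigurationError("lambda_max requires an L1 component (alpha > 0)")
    return float(np.max(np.abs(grad0)) / alpha)


def select_lambda_cv(
    X,
    time,
    event,
    kind: str = "elastic",
    alpha: float = 0.5,
    n_lambdas: int = 20,
    k: int = 5,
    seed: int = 0,
    lambda_min_ratio: float = 0.01,
) -> float:
    """Pick lambda by k-fold cross-validated partial-likelihood deviance.

    Uses the Verweij-van Houwelingen deviance -2 * [l_all(beta) - l_train(beta)],
    which stays defined when a held-out fold has few events.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    eff_alpha = {"ridge": 0.0, "lasso": 1.0}.get(kind, alpha)
    if eff_alpha > 0:
        lam_hi = lambda_max(X, time, event, eff_alpha)
    else:
        lam_hi = lambda_max(X, time, event, 1.0)  # same scale heuristic for ridge
    lambdas = np.geomspace(lam_hi, lam_hi * lambda_min_ratio, n_lambdas)
    rng = np.random.default_rng(seed)
    folds = rng.integers(1, k + 1, size=X.shape[0])
    scores = np.zeros(n_lambdas)
    for j, lam in enumerate(lambdas):
        dev = 0.0
        for f in range(1, k + 1):
            tr = folds != f
            if event[tr].sum() == 0:
                continue
            fit = fit_penalized_cox(X[tr], time[tr], event[tr], kind, lam, alpha)
            dev += -2 * (
                cox_partial_loglik(fit.beta, X, time, event)
                - cox_partial_loglik(fit.beta, X[tr], time[tr], event[tr])
            )
        scores[j] = dev
    best = int(np.argmin(scores))
    return float(lambdas[best])


def rank_sum_select(
    fold_fits: list[PenalizedCoxFit] | list[np.ndarray],
    gene_ids,
    top_k: int,
) -> pd.DataFrame:
    """Rank genes per fold by |beta| and select the smallest rank sums.

    Rank 1 is the largest |beta| within a fold (ties broken by gene ID);
    rank sums are totalled over folds and the ``top_k`` smallest sums are
    selected, ties broken by descending mean |beta|.
    """
    if len(fold_fits) == 0:
        raise ConfigurationError("rank_sum_select needs at least one fold fit")
    gene_ids = pd.Index(gene_ids)
    betas = np.column_stack(
        [f.beta if isinstance(f, PenalizedCoxFit) else np.asarray(f) for f in fold_fits]
    )
    if betas.shape[0] != len(gene_ids):
        raise ValidationError("beta length does not match gene list")
    table = pd.DataFrame({"gene": gene_ids})
    for f in range(betas.shape[1]):
        absb = np.abs(betas[:, f])
        order = np.lexsort((gene_ids.to_numpy(), -absb))
        ranks = np.empty(len(gene_ids), dtype=int)
        ranks[order] = np.arange(1, len(gene_ids) + 1)
        table[f"rank_fold{f + 1}"] = ranks
    rank_cols = [c for c in table.columns if c.startswith("rank_fold")]
    table["rank_sum"] = table[rank_cols].sum(axis=1)
    table["mean_abs_beta"] = np.abs(betas).mean(axis=1)
    table = table.sort_values(
        ["rank_sum", "mean_abs_beta", "gene"], ascending=[True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    table["selected"] = np.arange(len(table)) < min(top_k, len(table))
    return table
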