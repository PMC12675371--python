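"""Scoring and stratification harness for survival models.

Implements Harrell's concordance index, the IPCW (inverse probability of
censoring weighted) Brier score and its time-integrated version, prognostic
index (PI) stratification into 2 or 3 near-equal risk groups, k-group
log-rank testing (lifelines backend) and between-group hazard ratios from a
univariate Cox model.  ``evaluate_feature_set`` ties these together across
patient-grouped cross-validation folds and replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .cohort import Cohort
from .errors import ConfigurationError, ValidationError
from .models import MODEL_KINDS, make_model
from .preprocess import log_z_normalize, make_patient_folds

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054


def concordance_index(risk, time, event) -> float:
    """Harrell's C: over pairs with t_i < t_j and the earlier subject an
    event, the fraction where the earlier subject has the higher predicted
    risk; tied risks count 1/2."""
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not (risk.shape == time.shape == event.shape):
        raise ValidationError("risk/time/event lengths differ")
    earlier = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_usable = earlier.sum()
    if n_usable == 0:
        raise ValidationError("no usable pairs for the concordance index")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    score = (earlier & higher).sum() + 0.5 * (earlier & tied).sum()
    return float(score / n_usable)


def _censoring_survival(time, event):
    """KM estimate of the censoring distribution G (event indicator 1-delta)."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - np.asarray(event, int))
    sf = kmf.survival_function_
    return sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)


def _step_lookup(knots, values, t, left_limit=False):
    t = np.asarray(t, float)
    if left_limit:
        idx = np.searchsorted(knots, t, side="left") - 1
    else:
        idx = np.searchsorted(knots, t, side="right") - 1
    return np.where(idx >= 0, values[np.clip(idx, 0, None)], 1.0)


def brier_score(surv_at_t, time, event, t, censor_km=None) -> float:
    """IPCW Brier score at horizon ``t``.

    ``surv_at_t`` holds each subject's predicted S(t).  Subjects with an
    observed event by ``t`` contribute S(t)^2 weighted by 1/G(T_i-);
    subjects still under observation past ``t`` contribute (1 - S(t))^2
    weighted by 1/G(t); subjects censored before ``t`` get weight zero.
    """
    surv_at_t = np.asarray(surv_at_t, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    knots, g = censor_km if censor_km is not None else _censoring_survival(time, event)
    g_at_t = float(_step_lookup(knots, g, [t])[0])
    died = (time <= t) & (event == 1)
    alive = time > t
    if alive.any() and g_at_t <= 0:
        raise ValidationError(f"censoring survival G({t}) = 0; truncate the grid")
    g_before_death = _step_lookup(knots, g, time[died], left_limit=True)
    if died.any() and (g_before_death <= 0).any():
        raise ValidationError("censoring survival vanished before an event time")
    contrib = np.zeros_like(surv_at_t)
    contrib[died] = surv_at_t[died] ** 2 / g_before_death
    if alive.any():
        contrib[alive] = (1.0 - surv_at_t[alive]) ** 2 / g_at_t
    return float(contrib.mean())


def integrated_brier(survival_function, time, event) -> float:
    """Integrated Brier score over [0, max event time], trapezoid rule.

    ``survival_function(times)`` must return an (n_subjects, n_times)
    matrix.  The grid is the unique event times with 0 prepended; grid
    points where the censoring survival G vanishes are dropped (logged) and
    the integral is normalized by the last retained time.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    event_times = np.unique(time[event == 1])
    if event_times.size < 2:
        raise ValidationError("integrated Brier needs >= 2 distinct event times")
    knots, g = _censoring_survival(time, event)
    grid = np.r_[0.0, event_times]
    g_grid = _step_lookup(knots, g, grid)
    usable = (g_grid > 0) | ~np.array([(time > t).any() for t in grid])
    if not usable.all():
        logger.info(
            "integrated_brier: dropped %d grid points with G(t)=0", int((~usable).sum())
        )
        grid = grid[usable]
    surv = np.asarray(survival_function(grid), float)
    bs = np.array(
        [
            brier_score(surv[:, j], time, event, grid[j], censor_km=(knots, g))
            for j in range(len(grid))
        ]
    )
    return float(np.trapezoid(bs, grid) / grid[-1])


def prognostic_index(model, X) -> np.ndarray:
    """Per-sample scalar risk summary: the model's risk score.

    Linear predictor X beta for (penalized) Cox, ensemble mortality for the
    random survival forest, decision value for the survival SVM.
    """
    return np.asarray(model.risk_score(X), float)


def stratify_by_pi(pi, n_groups: int = 2) -> np.ndarray:
    """Split subjects into ``n_groups`` near-equal risk groups by PI rank.

    Group labels are 0 (lowest PI / low risk) upward; ties are resolved by
    stable rank order so group sizes differ by at most one.
    """
    pi = np.asarray(pi, float)
    if n_groups not in (2, 3):
        raise ConfigurationError("n_groups must be 2 or 3")
    if pi.size < n_groups:
        raise ValidationError("fewer subjects than groups")
    if np.ptp(pi) == 0:
        logger.warning("stratify_by_pi: all prognostic indices equal; rank-stable split")
    order = np.argsort(pi, kind="stable")
    labels = np.empty(pi.size, dtype=int)
    for g, chunk in enumerate(np.array_split(order, n_groups)):
        labels[chunk] = g
    return labels


def logrank_test(groups, time, event) -> tuple[float, float]:
    """Standard (unweighted) k-group log-rank test; chi-square with k-1 df."""
    groups = np.asarray(groups)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValidationError("log-rank test needs >= 2 non-empty groups")
    if event.sum() == 0:
        raise ValidationError("log-rank test needs >= 1 event")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class HazardRatioResult:
    hr: float
    ci_lower: float
    ci_upper: float
    flagged: bool = False  # unbounded/unstable (e.g. a group without events)


def group_hazard_ratio(groups, time, event) -> HazardRatioResult:
    """Univariate Cox hazard ratio of group 1 vs group 0 with a Wald 95% CI."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise ValidationError("group_hazard_ratio expects exactly 2 groups")
    indicator = (groups == uniq[1]).astype(float)
    event = np.asarray(event, int)
    flagged = any(event[groups == u].sum() == 0 for u in uniq)
    df = pd.DataFrame({"g": indicator, "time": np.asarray(time, float), "event": event})
    try:
        cph = CoxPHFitter().fit(df, "time", "event")
        beta = float(cph.params_["g"])
        se = float(cph.standard_errors_["g"])
    except ConvergenceError:
        logger.warning("group_hazard_ratio: Cox fit failed to converge; flagged")
        return HazardRatioResult(np.nan, 0.0, np.inf, flagged=True)
    return HazardRatioResult(
        hr=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - Z95 * se)),
        ci_upper=float(np.exp(beta + Z95 * se)),
        flagged=flagged,
    )


def evaluate_feature_set(
    cohort: Cohort,
    features,
    models=MODEL_KINDS,
    feature_set_name: str = "features",
    k: int = 5,
    replicates: int = 10,
    seed: int = 0,
    model_params: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-validated scoring and risk stratification of a gene set.

    For each replicate a fresh patient-grouped k-fold split is drawn; per
    fold, train and test sets are log2/z normalized separately, each model
    is fitted on the training samples and scored on the held-out samples
    (C-index, integrated Brier score), and the test-set prognostic indices
    are stratified into 2 and 3 risk groups with log-rank p-values and
    pairwise hazard ratios vs the low-risk group.

    Returns ``(metrics, stratification)`` DataFrames; summarize with
    :func:`summarize_metrics`.
    """
    features = list(features)
    missing = set(features) - set(cohort.expression.gene_ids)
    if missing:
        raise ValidationError(f"features not in the cohort: {sorted(missing)[:5]}")
    model_params = model_params or {}
    metrics_rows, strat_rows = [], []
    for rep in range(replicates):
        folds = make_patient_folds(cohort, k=k, seed=seed + rep)
        for fold in range(1, k + 1):
            train_ids, test_ids = folds.train_test_samples(cohort.clinical, fold)
            train = cohort.subset_samples(train_ids)
            test = cohort.subset_samples(test_ids)
            # train and test normalized separately, then restricted to features
            Xtr = log_z_normalize(train.expression).subset_genes(features).values.T
            Xte = log_z_normalize(test.expression).subset_genes(features).values.T
            t_tr = train.clinical["time"].to_numpy(float)
            e_tr = train.clinical["event"].to_numpy(int)
            t_te = test.clinical["time"].to_numpy(float)
            e_te = test.clinical["event"].to_numpy(int)
            if e_te.sum() == 0 or e_tr.sum() == 0:
                logger.warning("fold %d rep %d skipped: no events", fold, rep)
                continue
            for kind in models:
                model = make_model(kind, seed=seed + rep, **model_params.get(kind, {}))
                model.fit(Xtr, t_tr, e_tr)
                pi = prognostic_index(model, Xte)
                cidx = concordance_index(pi, t_te, e_te)
                ibs = integrated_brier(
                    lambda ts: model.survival_function(Xte, ts), t_te, e_te
                )
                metrics_rows.append(
                    {
                        "model": kind,
                        "feature_set": feature_set_name,
                        "replicate": rep,
                        "fold": fold,
                        "cindex": cidx,
                        "ibs": ibs,
                    }
                )
                for n_groups in (2, 3):
                    labels = stratify_by_pi(pi, n_groups)
                    stat, p = logrank_test(labels, t_te, e_te)
                    row = {
                        "model": kind,
                        "feature_set": feature_set_name,
                        "replicate": rep,
                        "fold": fold,
                        "n_groups": n_groups,
                        "logrank_stat": stat,
                        "logrank_p": p,
                    }
                    # pairwise HRs vs the low-risk reference group
                    for g in range(1, n_groups):
                        sel = (labels == 0) | (labels == g)
                        hr = group_hazard_ratio(labels[sel], t_te[sel], e_te[sel])
                        row[f"hr_group{g}_vs_0"] = hr.hr
                        row[f"hr_group{g}_ci_lower"] = hr.ci_lower
                        row[f"hr_group{g}_ci_upper"] = hr.ci_upper
                    strat_rows.append(row)
    return pd.DataFrame(metrics_rows), pd.DataFrame(strat_rows)


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of C-index and IBS per (model, feature set)."""
    return (
        metrics.groupby(["model", "feature_set"])
        .agg(
            cindex_mean=("cindex", "mean"),
            cindex_sd=("cindex", "std"),
            ibs_mean=("ibs", "mean"),
            ibs_sd=("ibs", "std"),
        )
        .reset_index()
    )


def summarize_stratification(strat: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the stratification log-rank p per (model, feature set, k)."""
    return (
        strat.groupby(["model", "feature_set", "n_groups"])
        .agg(logrank_p_mean=("logrank_p", "mean"), logrank_p_sd=("logrank_p", "std"))
        .reset_index()
    )
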