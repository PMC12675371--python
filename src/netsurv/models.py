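"""Survival model wrappers with a uniform risk-score / survival-function API.

Four model families are exposed behind one interface so the evaluation
harness can treat them interchangeably:

* ``cox_ph``      - Cox proportional hazards (lifelines);
* ``elastic_cox`` - elastic-net penalized Cox (netsurv's own solver) with a
                    Breslow baseline for survival curves;
* ``rsf``         - random survival forest (scikit-survival); its risk score
                    is the ensemble mortality, i.e. the tree-averaged
                    cumulative hazard summed over the event-time grid;
* ``surv_svm``    - linear ranking survival SVM (scikit-survival); it has no
                    native survival curves, so curves come from a univariate
                    Cox calibration of its decision values on the training
                    set.

``risk_score`` is always oriented so that higher values mean stochastically
shorter predicted survival; ``survival_function(X, times)`` returns an
(n_samples, n_times) matrix of S(t | x).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sksurv.ensemble import RandomSurvivalForest
from sksurv.svm import FastSurvivalSVM
from sksurv.util import Surv

from .errors import ConfigurationError, NetsurvError
from .penalized import fit_penalized_cox, select_lambda_cv

MODEL_KINDS = ("cox_ph", "elastic_cox", "rsf", "surv_svm")


class NotFittedError(NetsurvError):
    """Prediction was requested before the model was fitted."""


def breslow_cumulative_hazard(eta, time, event):
    """Breslow baseline cumulative hazard from a fitted linear predictor.

    Returns (event_times, H0) step-function knots: H0(t) jumps by
    d_k / sum_{risk set} exp(eta) at each distinct event time.
    """
    eta = np.asarray(eta, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(time, kind="stable")
    t, e, w = time[order], event[order], np.exp(eta[order])
    # at-risk sum of weights just before each position (suffix sums)
    suffix = np.cumsum(w[::-1])[::-1]
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e.astype(float), starts)
    denom = suffix[starts]
    uniq_t = t[starts]
    keep = d > 0
    increments = d[keep] / denom[keep]
    return uniq_t[keep], np.cumsum(increments)


def _step_eval(knots, values, t, before=0.0):
    """Right-continuous step function lookup (vectorized over t)."""
    idx = np.searchsorted(knots, np.asarray(t, float), side="right") - 1
    out = np.where(idx >= 0, values[np.clip(idx, 0, None)], before)
    return out


class _BaseModel:
    kind: str

    def __init__(self):
        self._fitted = False

    def _check_fitted(self):
        if not self._fitted:
            raise NotFittedError(f"{self.kind} model is not fitted")

    def fit(self, X, time, event):  # pragma: no cover - interface stub
        raise NotImplementedError

    def risk_score(self, X) -> np.ndarray:
        raise NotImplementedError

    def survival_function(self, X, times) -> np.ndarray:
        raise NotImplementedError


class _CoxCalibratedCurves:
    """Survival curves S(t|score) from a univariate Cox fit on a risk score.

    Used for models (the ranking SVM) that order patients but do not carry a
    time-to-event distribution of their own.
    """

    def fit(self, score, time, event):
        score = np.asarray(score, float)
        sd = score.std()
        self._scale = sd if sd > 0 else 1.0
        z = score / self._scale
        df = pd.DataFrame({"score": z, "time": time, "event": event})
        cph = CoxPHFitter()
        try:
            cph.fit(df, "time", "event")
        except ConvergenceError:
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, "time", "event")
        self._beta = float(cph.params_["score"])
        eta = self._beta * z
        self._knots, self._h0 = breslow_cumulative_hazard(eta, time, event)
        return self

    def survival(self, score, times):
        eta = self._beta * np.asarray(score, float) / self._scale
        h0 = _step_eval(self._knots, self._h0, times)
        return np.exp(-np.outer(np.exp(eta), h0))


class CoxPHModel(_BaseModel):
    """Cox proportional hazards (lifelines backend)."""

    kind = "cox_ph"

    def __init__(self, penalizer: float = 0.0):
        super().__init__()
        self.penalizer = penalizer

    def fit(self, X, time, event):
        X = np.atleast_2d(np.asarray(X, float))
        cols = [f"x{j}" for j in range(X.shape[1])]
        df = pd.DataFrame(X, columns=cols)
        df["time"] = np.asarray(time, float)
        df["event"] = np.asarray(event, int)
        cph = CoxPHFitter(penalizer=self.penalizer)
        try:
            cph.fit(df, "time", "event")
        except ConvergenceError:
            # near-collinear feature sets: retry with a light ridge term
            cph = CoxPHFitter(penalizer=max(self.penalizer, 0.1))
            cph.fit(df, "time", "event")
        self._cph = cph
        self._cols = cols
        self.beta = cph.params_.to_numpy()
        self._knots, self._h0 = breslow_cumulative_hazard(
            X @ self.beta, time, event
        )
        self._fitted = True
        return self

    def risk_score(self, X):
        self._check_fitted()
        return np.atleast_2d(np.asarray(X, float)) @ self.beta

    def survival_function(self, X, times):
        self._check_fitted()
        eta = self.risk_score(X)
        h0 = _step_eval(self._knots, self._h0, times)
        return np.exp(-np.outer(np.exp(eta), h0))


class ElasticCoxModel(_BaseModel):
    """Elastic-net Cox with Breslow baseline survival curves.

    ``lam=None`` triggers inner cross-validated selection on the training
    data; a fixed ``lam`` skips it.
    """

    kind = "elastic_cox"

    def __init__(self, lam: float | None = None, alpha: float = 0.5, seed: int = 0):
        super().__init__()
        self.lam = lam
        self.alpha = alpha
        self.seed = seed

    def fit(self, X, time, event):
        X = np.atleast_2d(np.asarray(X, float))
        lam = self.lam
        if lam is None:
            lam = select_lambda_cv(
                X, time, event, kind="elastic", alpha=self.alpha,
                n_lambdas=10, k=5, seed=self.seed,
            )
        self.fit_result = fit_penalized_cox(
            X, time, event, kind="elastic", lam=lam, alpha=self.alpha
        )
        self.beta = self.fit_result.beta
        self._knots, self._h0 = breslow_cumulative_hazard(X @ self.beta, time, event)
        self._fitted = True
        return self

    def risk_score(self, X):
        self._check_fitted()
        return np.atleast_2d(np.asarray(X, float)) @ self.beta

    def survival_function(self, X, times):
        self._check_fitted()
        h0 = _step_eval(self._knots, self._h0, times)
        return np.exp(-np.outer(np.exp(self.risk_score(X)), h0))


class RSFModel(_BaseModel):
    """Random survival forest (scikit-survival backend).

    Defaults: 500 trees, log-rank splitting, sqrt(p) features per split,
    bootstrap resampling per tree.  The risk score is the ensemble mortality
    (tree-averaged cumulative hazard summed over the event-time grid).
    """

    kind = "rsf"

    def __init__(self, n_estimators: int = 500, seed: int = 0, **kwargs):
        super().__init__()
        self._params = dict(
            n_estimators=n_estimators, max_features="sqrt", random_state=seed
        )
        self._params.update(kwargs)

    def fit(self, X, time, event):
        y = Surv.from_arrays(np.asarray(event, int).astype(bool), np.asarray(time, float))
        self._rsf = RandomSurvivalForest(**self._params).fit(np.atleast_2d(X), y)
        self._fitted = True
        return self

    def risk_score(self, X):
        self._check_fitted()
        return self._rsf.predict(np.atleast_2d(X))

    def survival_function(self, X, times):
        self._check_fitted()
        surv = self._rsf.predict_survival_function(np.atleast_2d(X), return_array=True)
        grid = self._rsf.unique_times_
        idx = np.searchsorted(grid, np.asarray(times, float), side="right") - 1
        out = np.ones((surv.shape[0], len(np.atleast_1d(times))))
        inside = idx >= 0
        out[:, inside] = surv[:, idx[inside]]
        return out


class SurvSVMModel(_BaseModel):
    """Linear ranking survival SVM (scikit-survival backend).

    Pure ranking objective (rank_ratio = 1) with regularization strength 1.0
    by default; the decision value is the risk score, and survival curves
    come from Cox calibration of that score on the training data.
    """

    kind = "surv_svm"

    def __init__(self, alpha: float = 1.0, seed: int = 0, **kwargs):
        super().__init__()
        self._params = dict(alpha=alpha, rank_ratio=1.0, random_state=seed, max_iter=100)
        self._params.update(kwargs)

    def fit(self, X, time, event):
        X = np.atleast_2d(np.asarray(X, float))
        y = Surv.from_arrays(np.asarray(event, int).astype(bool), np.asarray(time, float))
        self._svm = FastSurvivalSVM(**self._params).fit(X, y)
        self._calib = _CoxCalibratedCurves().fit(self._svm.predict(X), time, event)
        self._fitted = True
        return self

    def risk_score(self, X):
        self._check_fitted()
        return self._svm.predict(np.atleast_2d(X))

    def survival_function(self, X, times):
        self._check_fitted()
        return self._calib.survival(self.risk_score(X), times)


def make_model(kind: str, seed: int = 0, **kwargs) -> _BaseModel:
    """Factory for the four supported model kinds."""
    if kind == "cox_ph":
        return CoxPHModel(**kwargs)
    if kind == "elastic_cox":
        return ElasticCoxModel(seed=seed, **kwargs)
    if kind == "rsf":
        return RSFModel(seed=seed, **kwargs)
    if kind == "surv_svm":
        return SurvSVMModel(seed=seed, **kwargs)
    raise ConfigurationError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
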