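"""Survival machinery built from first principles.

Cox proportional-hazards regression (Newton-Raphson on the partial
likelihood, Breslow or Efron ties), evaluation of the partial likelihood
at fixed coefficients on *new* data (the quantity cross-validated during
model selection), Harrell's concordance index, Kaplan-Meier and reverse
Kaplan-Meier estimators, and Breslow baseline-hazard survival curves.

The estimator :class:`CoxPH` follows scikit-learn conventions (``fit``,
``predict`` returning the linear predictor, ``score`` returning the
concordance); the module-level functions are thin wrappers used by the
pipeline and the model-selection engine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _coxcore

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceError",
    "StepFunction",
    "CoxPH",
    "KMResult",
    "cox_fit",
    "cox_loglik",
    "c_harrell",
    "km",
    "reverse_km",
    "model_survival_curves",
    "as_time_event",
]

_TIES = {"breslow": _coxcore.BRESLOW, "efron": _coxcore.EFRON}


class ConvergenceError(RuntimeError):
    """Raised when the partial likelihood has no finite maximiser or the
    Newton iteration fails (e.g. monotone likelihood from a separating
    covariate)."""


class StepFunction:
    """Right-continuous step function with flat extension beyond the last knot."""

    def __init__(self, knots, values, initial: float = 1.0):
        self.knots = np.asarray(knots, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.knots.ndim != 1 or self.knots.shape != self.values.shape:
            raise ValueError("knots and values must be equal-length 1D arrays")
        if self.knots.size > 1 and np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        self.initial = float(initial)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t, side="right")
        full = np.concatenate([[self.initial], self.values])
        out = full[idx]
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.knots, "value": self.values})


def as_time_event(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce survival outcomes to ``(time, event)`` float/uint8 arrays.

    Accepts a ``(time, event)`` tuple, a DataFrame with ``time``/``event``
    columns (``time_months`` also recognised), or a structured array.
    """
    if isinstance(y, pd.DataFrame):
        tcol = "time" if "time" in y.columns else "time_months"
        time = y[tcol].to_numpy(dtype=float)
        event = y["event"].to_numpy()
    elif isinstance(y, tuple) and len(y) == 2:
        time, event = np.asarray(y[0], dtype=float), np.asarray(y[1])
    elif hasattr(y, "dtype") and getattr(y.dtype, "names", None):
        names = y.dtype.names
        time = np.asarray(y[names[1]] if "time" not in names else y["time"], dtype=float)
        event = np.asarray(y[names[0]] if "event" not in names else y["event"])
    else:
        raise TypeError("y must be (time, event), a DataFrame, or a structured array")
    event = np.asarray(event).astype(bool).astype(np.uint8)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    return time, event


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return np.ascontiguousarray(X.to_numpy(dtype=float)), [str(c) for c in X.columns]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and X.ndim == 2:
        pass
    return np.ascontiguousarray(X), [f"x{i}" for i in range(X.shape[1])]


def _sorted_desc(X, time, event):
    order = np.argsort(-time, kind="stable")
    return (
        np.ascontiguousarray(X[order]),
        np.ascontiguousarray(event[order]),
        np.ascontiguousarray(time[order]),
        order,
    )


class CoxPH(BaseEstimator):
    """Cox proportional-hazards model.

    Parameters
    ----------
    ties : {"breslow", "efron"}
        Tie handling in the partial likelihood.  Breslow is the default
        (it keeps the out-of-sample likelihood hand-checkable); Efron is
        available for cross-checks against other software.
    max_iter : int
    tol : float
        Convergence threshold on the max-norm of the score.

    Attributes
    ----------
    coef_ : ndarray — regression constants beta.
    param_names_ : list of str
    loglik_ : float — partial log-likelihood at the optimum.
    information_ : ndarray — observed information at the optimum.
    se_ : ndarray — Wald standard errors.
    baseline_cumhaz_ : StepFunction — Breslow baseline cumulative hazard.
    """

    def __init__(self, ties: str = "breslow", max_iter: int = 100, tol: float = 1e-8):
        self.ties = ties
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        if self.ties not in _TIES:
            raise ValueError("ties must be 'breslow' or 'efron'")
        Xm, names = _as_matrix(X)
        time, event = as_time_event(y)
        if Xm.shape[0] != time.size:
            raise ValueError("X and y have different numbers of patients")
        if event.sum() == 0:
            raise ValueError("no events in the data; the partial likelihood is empty")
        spans = np.ptp(Xm, axis=0)
        if np.any(spans == 0):
            bad = [names[i] for i in np.flatnonzero(spans == 0)]
            raise ValueError(f"constant columns cannot enter a Cox model: {bad}")
        Xs, es, ts, order = _sorted_desc(Xm, time, event)
        beta, ll, info, status = _coxcore.newton_fit(
            Xs, es, ts, _TIES[self.ties], self.max_iter, self.tol
        )
        if status == 2:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone partial likelihood: coefficient for '{worst}' diverges "
                "(separation)"
            )
        if status == 1:
            raise ConvergenceError("Newton iteration did not converge")
        # a monotone likelihood can plateau before |beta| blows up: the score
        # vanishes while the information collapses to ~0 relative to its
        # natural scale (number of events x covariate variance)
        info_scale = event.sum() * Xm.var(axis=0)
        degenerate = np.diag(info) < 1e-6 * info_scale
        if np.any(degenerate):
            worst = names[int(np.argmax(degenerate))]
            raise ConvergenceError(
                f"monotone partial likelihood: no finite maximiser for '{worst}' "
                "(separation)"
            )
        self.coef_ = beta
        self.param_names_ = names
        self.loglik_ = float(ll)
        self.information_ = info
        try:
            self.se_ = np.sqrt(np.diag(np.linalg.inv(info)))
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix at the optimum") from exc
        lp_sorted = Xs @ beta
        knots, cumhaz = _coxcore.breslow_cumhaz(ts, es, lp_sorted)
        self.baseline_cumhaz_ = StepFunction(knots, cumhaz, initial=0.0)
        self.n_events_ = int(event.sum())
        return self

    def predict(self, X) -> np.ndarray:
        """Linear predictor sum_j beta_j x_ij (log relative hazard)."""
        Xm, _ = _as_matrix(X)
        return Xm @ self.coef_

    def predict_survival_function(self, X) -> list[StepFunction]:
        """Per-patient survival curves S_i(t) = exp(-H0(t) * exp(lp_i))."""
        lp = self.predict(X)
        H0 = self.baseline_cumhaz_
        return [
            StepFunction(H0.knots, np.exp(-H0.values * np.exp(l)), initial=1.0)
            for l in lp
        ]

    def score(self, X, y) -> float:
        """Harrell's concordance index of the linear predictor."""
        time, event = as_time_event(y)
        return c_harrell(self.predict(X), time, event)

    @property
    def hazard_ratios_(self) -> np.ndarray:
        return np.exp(self.coef_)


def cox_fit(features, survival, subset: list[str] | None = None, ties: str = "breslow") -> CoxPH:
    """Fit a Cox model on (a subset of) a feature table."""
    X = features.data if hasattr(features, "data") else features
    if subset is not None:
        missing = [s for s in subset if s not in X.columns]
        if missing:
            raise KeyError(f"subset names not in the feature table: {missing}")
        X = X[list(subset)]
    return CoxPH(ties=ties).fit(X, survival)


def cox_loglik(beta, X, y, ties: str = "breslow") -> float:
    """Partial log-likelihood of ``(X, y)`` at fixed ``beta`` (no refit).

    With zero events (or no patients) the partial likelihood is an empty
    product; the value is defined as 0 and a warning is emitted because it
    degrades the per-patient normalisation used in cross-validation.
    """
    Xm, _ = _as_matrix(X)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if Xm.shape[0] == 0:
        warnings.warn("cox_loglik on empty data defined as 0", stacklevel=2)
        return 0.0
    time, event = as_time_event(y)
    if Xm.shape[1] != beta.size:
        raise ValueError("beta dimension does not match the number of columns")
    if event.sum() == 0:
        warnings.warn("cox_loglik with zero events defined as 0", stacklevel=2)
        return 0.0
    Xs, es, ts, _ = _sorted_desc(Xm, time, event)
    return float(_coxcore.loglik_only(Xs, es, ts, beta, _TIES[ties]))


def c_harrell(linear_predictors, time, event=None) -> float:
    """Harrell's concordance: the fraction of comparable patient pairs in
    which the patient with the lower linear predictor survives longer.

    A pair is comparable when the shorter time belongs to a patient with
    an event; equal times are excluded.  Tied predictors count 1/2.
    """
    if event is None:
        time, event = as_time_event(time)
    lp = np.asarray(linear_predictors, dtype=float)
    time = np.asarray(time, dtype=float)
    ev = np.asarray(event).astype(bool)
    shorter = time[:, None] < time[None, :]
    comparable = shorter & ev[:, None]
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = comparable & (lp[:, None] > lp[None, :])
    tied = comparable & (lp[:, None] == lp[None, :])
    return (int(conc.sum()) + 0.5 * int(tied.sum())) / n_comp


@dataclass
class KMResult:
    """Product-limit estimate with Greenwood log(-log) confidence bands.

    ``median_ci`` bounds are the first times at which the upper/lower
    confidence curve drops to 0.5; ``inf`` means not reached.
    """

    survival: StepFunction
    lower: StepFunction
    upper: StepFunction
    median: float
    median_ci: tuple[float, float]
    n_at_risk: np.ndarray
    n_events: np.ndarray


def km(y, alpha: float = 0.05) -> KMResult:
    """Kaplan-Meier estimator with log(-log)-transformed Greenwood CIs."""
    from scipy.stats import norm

    time, event = as_time_event(y)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq = np.unique(time)
    n = time.size
    S = 1.0
    green = 0.0
    z = norm.ppf(1 - alpha / 2)
    knots, surv, lo, hi, atrisk, nev = [], [], [], [], [], []
    for t in uniq:
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        if d == 0:
            continue
        S *= 1.0 - d / at_risk
        if at_risk > d:
            green += d / (at_risk * (at_risk - d))
        knots.append(t)
        surv.append(S)
        atrisk.append(at_risk)
        nev.append(d)
        if 0.0 < S < 1.0:
            se = np.sqrt(green) / abs(np.log(S))
            lo.append(S ** np.exp(z * se))
            hi.append(S ** np.exp(-z * se))
        else:
            lo.append(S)
            hi.append(S)
    knots = np.asarray(knots)
    surv = np.asarray(surv)
    lo = np.asarray(lo)
    hi = np.asarray(hi)

    def _first_leq(vals, threshold=0.5):
        idx = np.flatnonzero(vals <= threshold + 1e-12)
        return float(knots[idx[0]]) if idx.size else np.inf

    if knots.size == 0:
        empty = StepFunction(np.array([]), np.array([]), initial=1.0)
        return KMResult(empty, empty, empty, np.inf, (np.inf, np.inf),
                        np.array([], int), np.array([], int))
    return KMResult(
        survival=StepFunction(knots, surv, initial=1.0),
        lower=StepFunction(knots, lo, initial=1.0),
        upper=StepFunction(knots, hi, initial=1.0),
        median=_first_leq(surv),
        median_ci=(_first_leq(lo), _first_leq(hi)),
        n_at_risk=np.asarray(atrisk, int),
        n_events=np.asarray(nev, int),
    )


def reverse_km(y, alpha: float = 0.05) -> KMResult:
    """Median potential follow-up: KM with event and censoring roles swapped."""
    time, event = as_time_event(y)
    return km((time, 1 - event), alpha=alpha)


def model_survival_curves(model: CoxPH, X) -> list[StepFunction]:
    """Per-patient model survival curves from the Breslow baseline hazard."""
    return model.predict_survival_function(X)
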