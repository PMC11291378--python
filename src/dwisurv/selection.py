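"""Best-subset Cox model selection by bootstrap cross-validation.

For every candidate parameter subset, patients are resampled with
replacement; the in-boot patients fit the regression constants and the
partial likelihood of the *out-of-boot* patients at those constants is the
cross-validated score.  Because the out-of-boot count varies per boot, the
likelihood is normalised per out-of-boot patient (Schemper normalisation)
before averaging over the (default 50) bootstrap iterations.  The subset
with the best mean score wins and is refitted on the full cohort;
percentile confidence intervals for its coefficients come from 2000
further bootstraps.

The same bootstrap draws are reused for every subset (common random
numbers), so subset ranking is not blurred by resampling noise and the
whole search is deterministic given (data, configuration, seed).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from . import _coxcore
from .features import FeatureTable
from .survival import (
    KMResult,
    ConvergenceError,
    CoxPH,
    StepFunction,
    _sorted_desc,
    as_time_event,
    c_harrell,
    km,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SubsetScore",
    "SelectionResult",
    "CalibrationResult",
    "BestSubsetCoxCV",
    "cv_score",
    "best_subset_search",
    "bootstrap_ci",
    "calibration",
    "univariable_screen",
]

_TIES = {"breslow": _coxcore.BRESLOW, "efron": _coxcore.EFRON}


@dataclass
class SubsetScore:
    subset: tuple[str, ...]
    mean_cv_loglik: float
    n_iterations: int
    failures: int


@dataclass
class SelectionResult:
    best_subset: tuple[str, ...]
    final_model: CoxPH
    c_harrell: float
    all_scores: list[SubsetScore]
    seed: int | None
    beta_ci: dict[str, tuple[float, float]] | None = None

    def to_dict(self) -> dict:
        """JSON-serialisable summary (deterministic key order)."""
        return {
            "best_subset": list(self.best_subset),
            "beta": {
                name: float(b)
                for name, b in zip(self.final_model.param_names_, self.final_model.coef_)
            },
            "hazard_ratios": {
                name: float(h)
                for name, h in zip(
                    self.final_model.param_names_, self.final_model.hazard_ratios_
                )
            },
            "beta_ci": {k: [float(v[0]), float(v[1])] for k, v in self.beta_ci.items()}
            if self.beta_ci
            else None,
            "c_harrell": float(self.c_harrell),
            "mean_cv_loglik": float(
                max(s.mean_cv_loglik for s in self.all_scores)
            ),
            "n_subsets_evaluated": len(self.all_scores),
            "seed": self.seed,
        }


def _get_frame(features) -> pd.DataFrame:
    if isinstance(features, FeatureTable):
        return features.data
    return features


# --------------------------------------------------------------------------
# Bootstrap cross-validation engine (common random numbers across subsets)
# --------------------------------------------------------------------------

class _Draw:
    __slots__ = ("Xin", "es_in", "ts_in", "Xout", "es_out", "ts_out", "n_out")

    def __init__(self, X, time, event, in_idx, out_idx):
        self.Xin, self.es_in, self.ts_in, _ = _sorted_desc(
            X[in_idx], time[in_idx], event[in_idx]
        )
        self.Xout, self.es_out, self.ts_out, _ = _sorted_desc(
            X[out_idx], time[out_idx], event[out_idx]
        )
        self.n_out = out_idx.size


class _CVEngine:
    """Shared bootstrap draws + per-subset scoring.

    Draws that are degenerate for *any* subset (no out-of-boot patients,
    no in-boot or out-of-boot events) are rejected at generation time so
    every subset sees the same valid resamples.  Subset-specific failures
    (constant in-boot column, non-convergent fit) retry on deterministic
    extra draws for that iteration only.
    """

    def __init__(self, X, time, event, n_outer, seed, ties="breslow",
                 cv_loglik="oob", max_retries=10):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.time = time
        self.event = event
        self.n = time.size
        self.n_outer = int(n_outer)
        self.ties = _TIES[ties]
        self.cv_loglik = cv_loglik
        self.max_retries = max_retries
        children = np.random.SeedSequence(seed).spawn(self.n_outer)
        self._rngs = [np.random.default_rng(c) for c in children]
        self._draws: list[list[_Draw]] = [[] for _ in range(self.n_outer)]
        if cv_loglik == "vvh":
            self.X_full, self.es_full, self.ts_full, _ = _sorted_desc(
                self.X, time, event
            )

    def _new_valid_draw(self, rng) -> _Draw:
        for _ in range(1000):
            in_idx = rng.integers(0, self.n, self.n)
            out_mask = np.ones(self.n, dtype=bool)
            out_mask[in_idx] = False
            out_idx = np.flatnonzero(out_mask)
            if out_idx.size == 0:
                continue
            if self.event[in_idx].sum() == 0 or self.event[out_idx].sum() == 0:
                continue
            return _Draw(self.X, self.time, self.event, in_idx, out_idx)
        raise RuntimeError("could not draw a non-degenerate bootstrap resample")

    def draw(self, iteration: int, attempt: int) -> _Draw:
        cache = self._draws[iteration]
        while len(cache) <= attempt:
            cache.append(self._new_valid_draw(self._rngs[iteration]))
        return cache[attempt]

    def score(self, cols: np.ndarray, names: tuple[str, ...]) -> SubsetScore:
        lls = []
        failures = 0
        for it in range(self.n_outer):
            ok = False
            for attempt in range(self.max_retries):
                d = self.draw(it, attempt)
                Xin = np.ascontiguousarray(d.Xin[:, cols])
                if np.any(np.ptp(Xin, axis=0) == 0):
                    continue
                beta, ll_in, _, status = _coxcore.newton_fit(
                    Xin, d.es_in, d.ts_in, self.ties, 60, 1e-8
                )
                if status != 0:
                    continue
                Xout = np.ascontiguousarray(d.Xout[:, cols])
                if self.cv_loglik == "vvh":
                    ll_out = _coxcore.loglik_only(
                        np.ascontiguousarray(self.X_full[:, cols]),
                        self.es_full, self.ts_full, beta, self.ties,
                    ) - _coxcore.loglik_only(Xin, d.es_in, d.ts_in, beta, self.ties)
                else:
                    ll_out = _coxcore.loglik_only(
                        Xout, d.es_out, d.ts_out, beta, self.ties
                    )
                lls.append(ll_out / d.n_out)
                ok = True
                break
            if not ok:
                failures += 1
        if failures > self.n_outer / 2:
            raise ConvergenceError(
                f"subset {names} unscorable: {failures}/{self.n_outer} bootstrap "
                "iterations failed to fit"
            )
        if failures:
            logger.info("cv_score %s: %d failed iterations excluded", names, failures)
        return SubsetScore(
            subset=names,
            mean_cv_loglik=float(np.mean(lls)),
            n_iterations=len(lls),
            failures=failures,
        )


def cv_score(
    subset,
    features,
    survival,
    n_outer: int = 50,
    seed: int | None = None,
    ties: str = "breslow",
    cv_loglik: str = "oob",
) -> SubsetScore:
    """Bootstrap cross-validated, per-patient-normalised score of one subset."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if n_outer < 1:
        raise ValueError("n_outer must be >= 1")
    df = _get_frame(features)
    missing = [s for s in subset if s not in df.columns]
    if missing:
        raise KeyError(f"unknown parameters: {missing}")
    X = df.to_numpy(dtype=float)
    cols = np.array([df.columns.get_loc(s) for s in subset])
    if np.any(np.ptp(X[:, cols], axis=0) == 0):
        raise ValueError(f"constant column in subset {subset}")
    time, event = as_time_event(survival)
    engine = _CVEngine(X, time, event, n_outer, seed, ties=ties, cv_loglik=cv_loglik)
    return engine.score(cols, subset)


def best_subset_search(
    features,
    survival,
    candidate_params: list[str] | None = None,
    max_subset_size: int = 3,
    n_outer: int = 50,
    seed: int | None = None,
    ties: str = "breslow",
    cv_loglik: str = "oob",
    subset_budget: int = 20000,
    compute_ci: bool = False,
    n_boot_ci: int = 2000,
) -> SelectionResult:
    """Exhaustive best-subset search scored by bootstrap cross-validation.

    All subsets of size 1..max_subset_size of the candidate parameters are
    scored with shared bootstrap draws; the best mean cross-validated
    likelihood wins (ties broken toward the smaller subset, then
    lexicographically).  The winner is refitted on the full cohort.
    """
    if max_subset_size < 1:
        raise ValueError("max_subset_size must be >= 1")
    df = _get_frame(features)
    names = list(candidate_params) if candidate_params is not None else list(df.columns)
    missing = [s for s in names if s not in df.columns]
    if missing:
        raise KeyError(f"unknown candidate parameters: {missing}")
    import math

    n_subsets = sum(
        math.comb(len(names), s)
        for s in range(1, min(max_subset_size, len(names)) + 1)
    )
    if n_subsets > subset_budget:
        raise ValueError(
            f"{n_subsets} candidate subsets exceed the budget of {subset_budget}; "
            "lower max_subset_size or raise subset_budget"
        )
    X = df.to_numpy(dtype=float)
    time, event = as_time_event(survival)
    engine = _CVEngine(X, time, event, n_outer, seed, ties=ties, cv_loglik=cv_loglik)
    col_of = {s: df.columns.get_loc(s) for s in names}

    scores: list[SubsetScore] = []
    for size in range(1, min(max_subset_size, len(names)) + 1):
        for combo in itertools.combinations(sorted(names), size):
            cols = np.array([col_of[s] for s in combo])
            if np.any(np.ptp(X[:, cols], axis=0) == 0):
                logger.warning("skipping subset with constant column: %s", combo)
                continue
            try:
                scores.append(engine.score(cols, combo))
            except ConvergenceError as exc:
                logger.warning("subset %s excluded: %s", combo, exc)
    if not scores:
        raise ConvergenceError("no candidate subset could be scored")
    best = min(scores, key=lambda s: (-s.mean_cv_loglik, len(s.subset), s.subset))
    final = CoxPH(ties=ties).fit(df[list(best.subset)], (time, event))
    chc = c_harrell(final.predict(df[list(best.subset)]), time, event)
    result = SelectionResult(
        best_subset=best.subset,
        final_model=final,
        c_harrell=float(chc),
        all_scores=scores,
        seed=seed,
    )
    if compute_ci:
        result.beta_ci = bootstrap_ci(
            best.subset, features, survival, n_boot=n_boot_ci, seed=seed, ties=ties
        )
    return result


def bootstrap_ci(
    final_subset,
    features,
    survival,
    n_boot: int = 2000,
    seed: int | None = None,
    ties: str = "breslow",
    alpha: float = 0.05,
    max_failure_fraction: float = 0.10,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap confidence intervals for the final coefficients.

    The model is refitted on ``n_boot`` patient resamples; the CI is the
    central 1-alpha range of each coefficient's bootstrap distribution.
    Degenerate or non-convergent resamples are redrawn (logged); more than
    ``max_failure_fraction`` of failed draws aborts.
    """
    subset = tuple(final_subset)
    df = _get_frame(features)[list(subset)]
    X = np.ascontiguousarray(df.to_numpy(dtype=float))
    time, event = as_time_event(survival)
    # must fit on the full data first (errors propagate)
    CoxPH(ties=ties).fit(df, (time, event))
    rng = np.random.default_rng(seed)
    n = time.size
    betas = np.empty((n_boot, len(subset)))
    failures = 0
    max_failures = int(np.ceil(max_failure_fraction * n_boot))
    got = 0
    while got < n_boot:
        idx = rng.integers(0, n, n)
        if event[idx].sum() == 0:
            failures += 1
        else:
            Xb = X[idx]
            if np.any(np.ptp(Xb, axis=0) == 0):
                failures += 1
            else:
                Xs, es, ts, _ = _sorted_desc(Xb, time[idx], event[idx])
                beta, _, _, status = _coxcore.newton_fit(
                    np.ascontiguousarray(Xs), es, ts, _TIES[ties], 60, 1e-8
                )
                if status == 0:
                    betas[got] = beta
                    got += 1
                    continue
                failures += 1
        if failures > max_failures:
            raise ConvergenceError(
                f"more than {max_failure_fraction:.0%} of bootstrap refits failed"
            )
    if failures:
        logger.info("bootstrap_ci: %d failed resamples redrawn", failures)
    lo = np.percentile(betas, 100 * alpha / 2, axis=0)
    hi = np.percentile(betas, 100 * (1 - alpha / 2), axis=0)
    return {s: (float(l), float(h)) for s, l, h in zip(subset, lo, hi)}


@dataclass
class CalibrationResult:
    """Risk-group calibration of a fitted model.

    Groups are defined by the 25th/75th percentiles of the linear
    predictors; each group carries its Kaplan-Meier curve and the mean of
    its members' model survival curves.
    """

    labels: pd.Series
    thresholds: tuple[float, float]
    group_km: dict[str, KMResult]
    group_model_curve: dict[str, StepFunction]


def calibration(
    model: CoxPH,
    features,
    survival,
    quantiles: tuple[float, float] = (25.0, 75.0),
) -> CalibrationResult:
    """Split patients into low/medium/high risk and compare KM with the model.

    High risk: linear predictor above the upper percentile threshold; low
    risk: below the lower threshold; medium: in between (boundary values
    fall into the medium group).
    """
    df = _get_frame(features)
    X = df[model.param_names_] if isinstance(df, pd.DataFrame) else df
    lp = model.predict(X)
    if np.ptp(lp) == 0:
        raise ValueError(
            "all linear predictors are equal; the model does not discriminate "
            "and risk groups are undefined"
        )
    q_lo, q_hi = np.percentile(lp, quantiles)
    labels = np.where(lp > q_hi, "high", np.where(lp < q_lo, "low", "medium"))
    time, event = as_time_event(survival)
    curves = model.predict_survival_function(X)
    group_km: dict[str, KMResult] = {}
    group_curve: dict[str, StepFunction] = {}
    for g in ("low", "medium", "high"):
        sel = labels == g
        if not sel.any():
            continue
        if event[sel].sum() == 0:
            warnings.warn(f"risk group '{g}' has zero events; its KM curve is flat",
                          stacklevel=2)
        group_km[g] = km((time[sel], event[sel]))
        knots = model.baseline_cumhaz_.knots
        member_vals = np.vstack([c(knots) for c, s in zip(curves, sel) if s])
        group_curve[g] = StepFunction(knots, member_vals.mean(axis=0), initial=1.0)
    index = df.index if isinstance(df, pd.DataFrame) else pd.RangeIndex(len(lp))
    return CalibrationResult(
        labels=pd.Series(labels, index=index, name="risk_group"),
        thresholds=(float(q_lo), float(q_hi)),
        group_km=group_km,
        group_model_curve=group_curve,
    )


def univariable_screen(features, survival, ties: str = "breslow") -> pd.DataFrame:
    """One-parameter Cox models for every feature (forest-plot style table).

    Returns hazard ratios (per SD for standardized continuous features),
    Wald 95% CIs and p-values; parameters with divergent likelihood are
    flagged instead of reported.
    """
    df = _get_frame(features)
    time, event = as_time_event(survival)
    rows = []
    for col in df.columns:
        x = df[[col]]
        if np.ptp(x.to_numpy(dtype=float)) == 0:
            raise ValueError(f"parameter '{col}' is constant")
        try:
            model = CoxPH(ties=ties).fit(x, (time, event))
            beta, se = float(model.coef_[0]), float(model.se_[0])
            z = beta / se
            rows.append(
                {
                    "parameter": col,
                    "hr": float(np.exp(beta)),
                    "ci_lower": float(np.exp(beta - norm.ppf(0.975) * se)),
                    "ci_upper": float(np.exp(beta + norm.ppf(0.975) * se)),
                    "p": float(2 * norm.sf(abs(z))),
                    "diverged": False,
                }
            )
        except ConvergenceError:
            rows.append(
                {
                    "parameter": col,
                    "hr": np.nan,
                    "ci_lower": np.nan,
                    "ci_upper": np.nan,
                    "p": np.nan,
                    "diverged": True,
                }
            )
    return pd.DataFrame(rows).set_index("parameter")


class BestSubsetCoxCV(BaseEstimator):
    """sklearn-style wrapper around the best-subset search.

    ``fit(X, y)`` runs the search on a feature DataFrame (or
    :class:`FeatureTable`) and survival outcomes; the fitted attributes
    expose the winning subset and the full-cohort refit.
    """

    def __init__(
        self,
        max_subset_size: int = 3,
        n_outer: int = 50,
        n_boot_ci: int = 2000,
        compute_ci: bool = False,
        ties: str = "breslow",
        cv_loglik: str = "oob",
        random_state: int | None = None,
    ):
        self.max_subset_size = max_subset_size
        self.n_outer = n_outer
        self.n_boot_ci = n_boot_ci
        self.compute_ci = compute_ci
        self.ties = ties
        self.cv_loglik = cv_loglik
        self.random_state = random_state

    def fit(self, X, y):
        result = best_subset_search(
            X,
            y,
            max_subset_size=self.max_subset_size,
            n_outer=self.n_outer,
            seed=self.random_state,
            ties=self.ties,
            cv_loglik=self.cv_loglik,
            compute_ci=self.compute_ci,
            n_boot_ci=self.n_boot_ci,
        )
        self.result_ = result
        self.best_subset_ = result.best_subset
        self.best_estimator_ = result.final_model
        self.scores_ = result.all_scores
        self.c_harrell_ = result.c_harrell
        return self

    def predict(self, X):
        df = _get_frame(X)
        return self.best_estimator_.predict(df[list(self.best_subset_)])

    def score(self, X, y):
        time, event = as_time_event(y)
        return c_harrell(self.predict(X), time, event)
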