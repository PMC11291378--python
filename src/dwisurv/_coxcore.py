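"""Low-level Cox partial-likelihood kernels (numba-compiled).

All kernels operate on data pre-sorted by survival time in *descending*
order, so the risk set at each event time is a running prefix.  Both
Breslow and Efron tie handling are provided; with no tied event times the
two coincide.

Fit status codes returned by :func:`newton_fit`:
0 = converged, 1 = max iterations reached, 2 = coefficients diverged
(monotone likelihood / separation).
"""

from __future__ import annotations

import numpy as np
from numba import njit

BRESLOW = 0
EFRON = 1


@njit(cache=False)
def loglik_score_info(X, event, time, beta, ties):
    """Partial log-likelihood, score and information at ``beta``.

    ``X`` (n, p), ``event`` uint8, ``time`` float — all sorted by time
    descending.  Returns (loglik, score, info).
    """
    n, p = X.shape
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        # add the tie group to the risk set; accumulate event sums
        d = 0
        t0 = 0.0
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        for m in range(i, j):
            lp = 0.0
            for q in range(p):
                lp += X[m, q] * beta[q]
            w = np.exp(lp)
            s0 += w
            for q in range(p):
                s1[q] += w * X[m, q]
                for r in range(p):
                    s2[q, r] += w * X[m, q] * X[m, r]
            if event[m]:
                d += 1
                ll += lp
                t0 += w
                for q in range(p):
                    score[q] += X[m, q]
                    t1[q] += w * X[m, q]
                    for r in range(p):
                        t2[q, r] += w * X[m, q] * X[m, r]
        if d > 0:
            if ties == 0:  # Breslow: full risk set for every tied event
                for _ in range(d):
                    ll -= np.log(s0)
                    for q in range(p):
                        score[q] -= s1[q] / s0
                        for r in range(p):
                            info[q, r] += s2[q, r] / s0 - s1[q] * s1[r] / (s0 * s0)
            else:  # Efron correction
                for l in range(d):
                    f = l / d
                    d0 = s0 - f * t0
                    ll -= np.log(d0)
                    for q in range(p):
                        d1q = s1[q] - f * t1[q]
                        score[q] -= d1q / d0
                        for r in range(p):
                            d1r = s1[r] - f * t1[r]
                            d2 = s2[q, r] - f * t2[q, r]
                            info[q, r] += d2 / d0 - d1q * d1r / (d0 * d0)
        i = j
    return ll, score, info


@njit(cache=False)
def loglik_only(X, event, time, beta, ties):
    """Partial log-likelihood at fixed ``beta`` (no derivatives)."""
    n, p = X.shape
    ll = 0.0
    s0 = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = 0
        t0 = 0.0
        for m in range(i, j):
            lp = 0.0
            for q in range(p):
                lp += X[m, q] * beta[q]
            w = np.exp(lp)
            s0 += w
            if event[m]:
                d += 1
                ll += lp
                t0 += w
        if d > 0:
            if ties == 0:
                ll -= d * np.log(s0)
            else:
                for l in range(d):
                    ll -= np.log(s0 - (l / d) * t0)
        i = j
    return ll


@njit(cache=False)
def newton_fit(X, event, time, ties, max_iter, tol):
    """Newton-Raphson maximisation of the partial likelihood from beta = 0.

    Step-halving safeguards each iteration; a tiny relative ridge keeps the
    step solvable when the information matrix is near-singular (the final
    reported information matrix is un-ridged).

    Returns (beta, loglik, info, status).
    """
    n, p = X.shape
    beta = np.zeros(p)
    ll, score, info = loglik_score_info(X, event, time, beta, ties)
    status = 1
    for _ in range(max_iter):
        smax = 0.0
        for q in range(p):
            if abs(score[q]) > smax:
                smax = abs(score[q])
        if smax < tol:
            status = 0
            break
        # ridge scaled to the information diagonal, solvability only
        tr = 0.0
        for q in range(p):
            tr += info[q, q]
        ridge = 1e-10 * (tr / p + 1.0)
        A = info.copy()
        for q in range(p):
            A[q, q] += ridge
        step = np.linalg.solve(A, score)
        # step halving until the likelihood does not decrease
        new_beta = beta + step
        new_ll = loglik_only(X, event, time, new_beta, ties)
        halves = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halves < 40:
            step = step / 2.0
            new_beta = beta + step
            new_ll = loglik_only(X, event, time, new_beta, ties)
            halves += 1
        beta = new_beta
        bmax = 0.0
        stepmax = 0.0
        for q in range(p):
            if abs(beta[q]) > bmax:
                bmax = abs(beta[q])
            if abs(step[q]) > stepmax:
                stepmax = abs(step[q])
        if bmax > 50.0:
            status = 2
            ll = new_ll
            break
        ll, score, info = loglik_score_info(X, event, time, beta, ties)
        if stepmax < 1e-10:
            smax = 0.0
            for q in range(p):
                if abs(score[q]) > smax:
                    smax = abs(score[q])
            # the score is a sum of O(n) terms, so its floating-point noise
            # floor scales with the likelihood magnitude; beta itself is
            # already converged to 1e-10 when the step is this small
            status = 0 if smax < 1e-6 * (1.0 + abs(ll)) else 1
            break
    return beta, ll, info, status


@njit(cache=False)
def breslow_cumhaz(time, event, lp):
    """Breslow baseline cumulative hazard at the distinct event times.

    Inputs sorted by time descending.  Returns (event_times ascending,
    cumulative hazard values).
    """
    n = time.shape[0]
    max_knots = 0
    for i in range(n):
        if event[i]:
            max_knots += 1
    knots = np.empty(max_knots)
    incr = np.empty(max_knots)
    s0 = 0.0
    nk = 0
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = 0
        for m in range(i, j):
            s0 += np.exp(lp[m])
            if event[m]:
                d += 1
        if d > 0:
            knots[nk] = time[i]
            incr[nk] = d / s0
            nk += 1
        i = j
    # knots were produced descending; reverse and accumulate
    out_t = np.empty(nk)
    out_h = np.empty(nk)
    acc = 0.0
    for q in range(nk):
        out_t[q] = knots[nk - 1 - q]
    for q in range(nk):
        acc += incr[nk - 1 - q]
        out_h[q] = acc
    return out_t, out_h
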