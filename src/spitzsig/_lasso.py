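"""Coordinate-descent solvers for the L1-penalized path.

Two interchangeable implementations of the same cyclic coordinate descent
with warm starts over a descending lambda grid: a numba kernel (fast path)
and a plain-Python mirror that can assert, sweep by sweep, that the working
penalized weighted-least-squares objective never increases (debug path).
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: glmnet-style clamps on the IRLS working quantities
_MU_EPS = 1e-5
_W_MIN = 1e-5

_MAX_OUTER = 100
_MAX_INNER = 1000


@njit(cache=True, inline="always")
def _update_coord(X, w, r, v, beta, lam, n, j):
    """One coordinate update; returns |change|."""
    if v[j] < 1e-12:
        return 0.0
    g = 0.0
    for i in range(n):
        g += w[i] * X[i, j] * r[i]
    a = g / n + v[j] * beta[j]
    if a > lam:
        new = (a - lam) / v[j]
    elif a < -lam:
        new = (a + lam) / v[j]
    else:
        new = 0.0
    d = new - beta[j]
    if d != 0.0:
        for i in range(n):
            r[i] -= X[i, j] * d
        beta[j] = new
    return abs(d)


@njit(cache=True, inline="always")
def _update_intercept(w, r, n):
    sw = 0.0
    swr = 0.0
    for i in range(n):
        sw += w[i]
        swr += w[i] * r[i]
    d0 = swr / sw
    if d0 != 0.0:
        for i in range(n):
            r[i] -= d0
    return d0


@njit(cache=True, inline="always")
def _linear_predictor(X, beta, b0, eta, n, p):
    for i in range(n):
        eta[i] = b0
    for j in range(p):
        bj = beta[j]
        if bj != 0.0:
            for i in range(n):
                eta[i] += X[i, j] * bj


@njit(cache=True, inline="always")
def _gradient(X, y, eta, gaussian, grad, n, p):
    """Unpenalized-loss gradient wrt beta at the current linear predictor."""
    res = np.empty(n)
    if gaussian:
        for i in range(n):
            res[i] = eta[i] - y[i]
    else:
        for i in range(n):
            res[i] = 1.0 / (1.0 + np.exp(-eta[i])) - y[i]
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * res[i]
        grad[j] = s / n


@njit(cache=True)
def _cd_path_numba(X, y, lambdas, gaussian, tol):  # pragma: no cover - numba
    n, p = X.shape
    nl = lambdas.size
    coefs = np.zeros((nl, p))
    intercepts = np.zeros(nl)
    beta = np.zeros(p)
    ybar = y.mean()
    if gaussian:
        b0 = ybar
    else:
        b0 = np.log(ybar / (1.0 - ybar))

    eta = np.empty(n)
    grad = np.empty(p)
    for li in range(nl):
        lam = lambdas[li]
        lam_prev = lambdas[li - 1] if li > 0 else lambdas[0]
        # sequential strong rule: screen on the gradient at the warm start
        _linear_predictor(X, beta, b0, eta, n, p)
        _gradient(X, y, eta, gaussian, grad, n, p)
        screened = np.zeros(p, dtype=np.bool_)
        thresh = 2.0 * lam - lam_prev
        for j in range(p):
            if beta[j] != 0.0 or abs(grad[j]) >= thresh:
                screened[j] = True
        for _kkt_round in range(100):
            sj = np.flatnonzero(screened)
            for _outer in range(_MAX_OUTER):
                # working response and weights at the current linear predictor
                _linear_predictor(X, beta, b0, eta, n, p)
                w = np.empty(n)
                z = np.empty(n)
                if gaussian:
                    for i in range(n):
                        w[i] = 1.0
                        z[i] = y[i]
                else:
                    for i in range(n):
                        mu = 1.0 / (1.0 + np.exp(-eta[i]))
                        if mu < _MU_EPS:
                            mu = _MU_EPS
                        elif mu > 1.0 - _MU_EPS:
                            mu = 1.0 - _MU_EPS
                        wi = mu * (1.0 - mu)
                        if wi < _W_MIN:
                            wi = _W_MIN
                        w[i] = wi
                        z[i] = eta[i] + (y[i] - mu) / wi
                v = np.zeros(p)
                for j in sj:
                    s = 0.0
                    for i in range(n):
                        s += w[i] * X[i, j] * X[i, j]
                    v[j] = s / n
                r = np.empty(n)
                for i in range(n):
                    r[i] = z[i] - eta[i]
                beta_outer = beta.copy()
                b0_outer = b0
                # screened sweeps alternating with sweeps over the active set
                for _round in range(_MAX_INNER):
                    maxd = 0.0
                    for j in sj:
                        d = _update_coord(X, w, r, v, beta, lam, n, j)
                        if d > maxd:
                            maxd = d
                    d0 = _update_intercept(w, r, n)
                    b0 += d0
                    if abs(d0) > maxd:
                        maxd = abs(d0)
                    if maxd < tol:
                        break
                    active = np.flatnonzero(beta)
                    for _asweep in range(_MAX_INNER):
                        maxd_a = 0.0
                        for j in active:
                            d = _update_coord(X, w, r, v, beta, lam, n, j)
                            if d > maxd_a:
                                maxd_a = d
                        d0 = _update_intercept(w, r, n)
                        b0 += d0
                        if abs(d0) > maxd_a:
                            maxd_a = abs(d0)
                        if maxd_a < tol:
                            break
                if gaussian:
                    break
                chg = abs(b0 - b0_outer)
                for j in range(p):
                    d = abs(beta[j] - beta_outer[j])
                    if d > chg:
                        chg = d
                if chg < tol:
                    break
            # KKT check over the unscreened coordinates
            _linear_predictor(X, beta, b0, eta, n, p)
            _gradient(X, y, eta, gaussian, grad, n, p)
            violations = 0
            for j in range(p):
                if not screened[j] and abs(grad[j]) > lam + 1e-12:
                    screened[j] = True
                    violations += 1
            if violations == 0:
                break
        for j in range(p):
            coefs[li, j] = beta[j]
        intercepts[li] = b0
    return coefs, intercepts


def _wls_objective(X, y_work, w, b0, beta, lam):
    r = y_work - b0 - X @ beta
    return 0.5 * np.mean(w * r**2) + lam * np.abs(beta).sum()


def _cd_path_python(X, y, lambdas, gaussian, tol, assert_monotone=True):
    """Reference implementation; asserts the per-sweep objective is monotone."""
    n, p = X.shape
    nl = lambdas.size
    coefs = np.zeros((nl, p))
    intercepts = np.zeros(nl)
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = ybar if gaussian else float(np.log(ybar / (1.0 - ybar)))

    for li, lam in enumerate(lambdas):
        for _outer in range(_MAX_OUTER):
            eta = b0 + X @ beta
            if gaussian:
                w = np.ones(n)
                z = y.astype(float)
            else:
                mu = np.clip(1.0 / (1.0 + np.exp(-eta)), _MU_EPS, 1.0 - _MU_EPS)
                w = np.maximum(mu * (1.0 - mu), _W_MIN)
                z = eta + (y - mu) / w
            v = (w[:, None] * X**2).mean(axis=0)
            r = z - eta
            beta_outer, b0_outer = beta.copy(), b0
            prev_obj = _wls_objective(X, z, w, b0, beta, lam)
            for _inner in range(_MAX_INNER):
                maxd = 0.0
                for j in range(p):
                    if v[j] < 1e-12:
                        continue
                    a = np.mean(w * X[:, j] * r) + v[j] * beta[j]
                    new = np.sign(a) * max(abs(a) - lam, 0.0) / v[j]
                    d = new - beta[j]
                    if d != 0.0:
                        r = r - X[:, j] * d
                        beta[j] = new
                        maxd = max(maxd, abs(d))
                d0 = np.sum(w * r) / np.sum(w)
                if d0 != 0.0:
                    b0 += d0
                    r = r - d0
                    maxd = max(maxd, abs(d0))
                if assert_monotone:
                    obj = _wls_objective(X, z, w, b0, beta, lam)
                    assert obj <= prev_obj + 1e-10, (
                        f"objective increased within a sweep: {prev_obj} -> {obj}"
                    )
                    prev_obj = obj
                if maxd < tol:
                    break
            if gaussian:
                break
            chg = max(abs(b0 - b0_outer), np.max(np.abs(beta - beta_outer), initial=0.0))
            if chg < tol:
                break
        coefs[li] = beta
        intercepts[li] = b0
    return coefs, intercepts
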