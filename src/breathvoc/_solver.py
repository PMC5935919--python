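"""Numerical kernels for weighted-L1 penalized logistic regression.

The objective minimized is

    f(b0, beta) = -loglik(b0, beta) + lambda * sum_j w_j * |beta_j|

with the log-likelihood summed (not averaged) over observations and the
intercept b0 unpenalized.  w_j = inf forces beta_j = 0.  The algorithm is
proximal Newton: an outer iteratively-reweighted least-squares loop around a
cyclic coordinate-descent solve of the penalized weighted least-squares
subproblem (the glmnet scheme).  Kernels are numba-compiled; everything here
operates on plain float64 arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# IRLS working weights are floored to keep the quadratic subproblem bounded
# when fitted probabilities saturate.
_WMIN = 1e-6


@njit(cache=True)
def _soft_threshold(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(cache=True)
def _cd_wls(X, z, w, pen, beta, b0, tol, max_sweeps):
    """Coordinate descent on 0.5*sum_i w_i (z_i - b0 - x_i.beta)^2 + sum_j pen_j |beta_j|.

    ``pen`` carries lambda*w_j per feature (inf allowed).  beta/b0 are updated
    in place-style and returned; the residual r = z - b0 - X beta is maintained
    incrementally.
    """
    n, p = X.shape
    r = z - b0 - X @ beta
    wsum = w.sum()
    denom = np.empty(p)
    for j in range(p):
        d = 0.0
        for i in range(n):
            d += w[i] * X[i, j] * X[i, j]
        denom[j] = d
    for _ in range(max_sweeps):
        delta = 0.0
        # intercept (unpenalized)
        db0 = 0.0
        for i in range(n):
            db0 += w[i] * r[i]
        db0 /= wsum
        if db0 != 0.0:
            b0 += db0
            for i in range(n):
                r[i] -= db0
            delta = max(delta, abs(db0))
        for j in range(p):
            if not np.isfinite(pen[j]):
                if beta[j] != 0.0:
                    for i in range(n):
                        r[i] += X[i, j] * beta[j]
                    beta[j] = 0.0
                continue
            if denom[j] <= 0.0:
                continue
            rho = 0.0
            for i in range(n):
                rho += w[i] * X[i, j] * r[i]
            rho += denom[j] * beta[j]
            bnew = _soft_threshold(rho, pen[j]) / denom[j]
            diff = bnew - beta[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * diff
                beta[j] = bnew
                delta = max(delta, abs(diff))
        if delta < tol:
            break
    return beta, b0


@njit(cache=True)
def _logistic_irls(X, y, lam, pen_w, beta, b0, kkt_tol, max_outer, cd_tol, cd_sweeps):
    """Proximal-Newton solve; returns (beta, b0, n_outer, kkt_residual)."""
    n, p = X.shape
    pen = np.empty(p)
    for j in range(p):
        pen[j] = lam * pen_w[j] if np.isfinite(pen_w[j]) else np.inf
    kkt = np.inf
    it = 0
    for it in range(1, max_outer + 1):
        eta = b0 + X @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        w = prob * (1.0 - prob)
        z = np.empty(n)
        for i in range(n):
            wi = w[i]
            if wi < _WMIN:
                wi = _WMIN
                w[i] = wi
            z[i] = eta[i] + (y[i] - prob[i]) / wi
        beta, b0 = _cd_wls(X, z, w, pen, beta, b0, cd_tol, cd_sweeps)
        # KKT residual of the *logistic* objective at the new point
        eta = b0 + X @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        resid = y - prob
        kkt = abs(resid.sum())  # intercept stationarity
        for j in range(p):
            g = 0.0
            for i in range(n):
                g += X[i, j] * resid[i]
            if not np.isfinite(pen[j]):
                continue
            if beta[j] == 0.0:
                v = abs(g) - pen[j]
                if v > kkt:
                    kkt = v
            else:
                s = 1.0 if beta[j] > 0.0 else -1.0
                v = abs(g - pen[j] * s)
                if v > kkt:
                    kkt = v
        if kkt <= kkt_tol:
            break
    return beta, b0, it, kkt


def neg_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray, b0: float) -> float:
    """Summed negative Bernoulli log-likelihood (numerically stable)."""
    eta = b0 + X @ beta
    # log(1+e^eta) - y*eta, stable for large |eta|
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def penalized_objective(X, y, beta, b0, lam, pen_w) -> float:
    pen_w = np.asarray(pen_w, dtype=float)
    active = np.isfinite(pen_w)
    return neg_loglik(X, y, beta, b0) + lam * float(
        np.sum(pen_w[active] * np.abs(beta[active]))
    )


def kkt_residual(X, y, beta, b0, lam, pen_w) -> float:
    """Maximal violation of the subgradient optimality conditions.

    Independent of the solver loop: recomputed from scratch in pure numpy.
    """
    from scipy.special import expit

    eta = b0 + X @ beta
    prob = expit(eta)
    resid = y - prob
    g = X.T @ resid
    viol = abs(float(resid.sum()))
    for j in range(X.shape[1]):
        pj = lam * pen_w[j]
        if not np.isfinite(pj):
            continue
        if beta[j] == 0.0:
            viol = max(viol, abs(g[j]) - pj)
        else:
            viol = max(viol, abs(g[j] - pj * np.sign(beta[j])))
    return viol
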