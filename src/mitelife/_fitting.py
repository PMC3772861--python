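"""Shared maximum-likelihood machinery: bounded quasi-Newton optimization with
warm starts and seeded restarts, and finite-difference observed information."""

from __future__ import annotations

import numpy as np
from scipy import optimize


def maximize(negloglik, theta0, bounds, jac=None, restarts=0, seed=0, jitter=0.3,
             ftol=1e-12, gtol=1e-6, maxiter=500):
    """Maximize ``-negloglik`` by L-BFGS-B from ``theta0`` plus seeded jittered
    restarts; returns the best ``OptimizeResult``."""
    theta0 = np.asarray(theta0, dtype=float)
    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(restarts + 1):
        x0 = theta0 if trial == 0 else np.clip(theta0 + jitter * rng.standard_normal(theta0.size), lb, ub)
        try:
            res = optimize.minimize(
                negloglik, x0, jac=jac, method="L-BFGS-B", bounds=bounds,
                options={"ftol": ftol, "gtol": gtol, "maxiter": maxiter},
            )
        except (FloatingPointError, ValueError):  # pragma: no cover - defensive
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None:
        res = optimize.OptimizeResult(x=theta0, fun=np.inf, success=False, message="all starts failed")
        return res
    return best


def fd_hessian(fun, theta, active=None, rel_step=1e-4):
    """Central finite-difference Hessian of ``fun`` over ``active`` indices.

    Entries for inactive parameters (e.g. variance components estimated at the
    boundary) are left at zero; callers invert with a pseudo-inverse.
    """
    theta = np.asarray(theta, dtype=float)
    p = theta.size
    if active is None:
        active = np.arange(p)
    active = np.asarray(active, dtype=int)
    h = rel_step * np.maximum(1.0, np.abs(theta))
    H = np.zeros((p, p))
    f0 = fun(theta)
    for ai, i in enumerate(active):
        ei = np.zeros(p)
        ei[i] = h[i]
        fpp = fun(theta + ei)
        fmm = fun(theta - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / (h[i] * h[i])
        for j in active[ai + 1:]:
            ej = np.zeros(p)
            ej[j] = h[j]
            fij = fun(theta + ei + ej) - fun(theta + ei - ej) - fun(theta - ei + ej) + fun(theta - ei - ej)
            H[i, j] = H[j, i] = fij / (4.0 * h[i] * h[j])
    return H


def vcov_from_hessian(H, active=None):
    """Covariance = pseudo-inverse of the observed information restricted to
    the active block; symmetric by construction."""
    p = H.shape[0]
    if active is None:
        active = np.arange(p)
    active = np.asarray(active, dtype=int)
    V = np.zeros((p, p))
    block = H[np.ix_(active, active)]
    try:
        Vb = np.linalg.pinv(0.5 * (block + block.T))
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        Vb = np.full_like(block, np.nan)
    V[np.ix_(active, active)] = 0.5 * (Vb + Vb.T)
    return V
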