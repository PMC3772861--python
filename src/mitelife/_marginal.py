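"""Marginal likelihood over nested Normal random effects by Gauss-Hermite
quadrature.

Shared numerical core for the Weibull time-to-event model and the GLMMs. All
three models have a linear predictor ``eta_r = x_r' b + u_{c(r)} + v_r`` with
``u_c ~ N(0, sigma_colony^2)`` shared within a colony and an independent
``v_r ~ N(0, sigma_assay^2)`` per row (assay population). The marginal
log-likelihood is

    sum_c log int phi(u; s_c) prod_{r in c} [ int phi(v; s_a) e^{f_r(eta0_r + u + v)} dv ] du

where ``f_r`` is the conditional log-likelihood of row ``r``. Two quadrature
schemes are provided:

* ``"gh"``: plain Gauss-Hermite with prior-scaled nodes at both levels;
* ``"agh"`` (default): adaptive Gauss-Hermite, centering and scaling the nodes
  at the conditional mode of each integrand (found by damped Newton using the
  analytic first two derivatives of ``f_r``), at both levels. The outer-level
  derivatives of the inner integrals are obtained as posterior moments of
  ``f'`` and ``f''`` under the inner quadrature weights.

The row likelihood is supplied as ``fgh(s, deriv)`` returning ``(f, g, H)``
with ``g = H = None`` when ``deriv`` is false; ``s`` has shape ``(R, ...)``
and the callable must broadcast its per-row data over trailing axes.

Either standard deviation may be exactly zero, in which case the
corresponding integral degenerates to a point mass; this makes boundary
estimates representable exactly.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

SIGMA_ZERO = 1e-10
_SQRT2 = np.sqrt(2.0)
_LOG_SQRT2 = 0.5 * np.log(2.0)
_LOG_SQRT2PI = 0.5 * np.log(2.0 * np.pi)


@lru_cache(maxsize=64)
def gauss_hermite(order: int):
    """Nodes/weights for ``int e^{-x^2} f(x) dx``; cached per order."""
    if order < 1:
        raise ValueError("quadrature order must be >= 1")
    z, w = np.polynomial.hermite.hermgauss(order)
    return z, w, np.log(w)


def _colony_sum(values: np.ndarray, colony_idx: np.ndarray, n_colonies: int) -> np.ndarray:
    out = np.zeros((n_colonies,) + values.shape[1:])
    np.add.at(out, colony_idx, values)
    return out


def _sanitize(f, g=None, H=None):
    f = np.where(np.isnan(f), -np.inf, f)
    if g is not None:
        g = np.nan_to_num(g, nan=0.0, posinf=0.0, neginf=0.0)
    if H is not None:
        H = np.nan_to_num(H, nan=-1.0, posinf=-1.0, neginf=-1e30)
    return f, g, H


def _inner_agh(fgh, eta, sigma, z, logw, mode0=None, need_moments=False,
               max_newton=50, tol=1e-10):
    """Adaptive GH integral of ``phi(v; sigma) e^{f(eta + v)}`` over v.

    Returns ``(logI, mode, dlogI, d2logI)``; the derivative pair (with respect
    to a shift of ``eta``) is ``None`` unless ``need_moments`` is set.
    """
    prec = 1.0 / (sigma * sigma)
    if mode0 is not None and np.shape(mode0) == np.shape(eta):
        m = np.array(mode0, dtype=float, copy=True)
    else:
        m = np.zeros_like(eta, dtype=float)
    hess = np.full_like(m, -prec)
    for _ in range(max_newton):
        f, g, H = fgh(eta + m, True)
        _, g, H = _sanitize(f, g, H)
        hess = np.minimum(H - prec, -1e-8)
        step = np.clip(-(g - m * prec) / hess, -4.0, 4.0)
        m = m + step
        if np.max(np.abs(step)) < tol:
            break
    tau = 1.0 / np.sqrt(-hess)
    nodes = m[..., None] + _SQRT2 * tau[..., None] * z
    s = eta[..., None] + nodes
    if need_moments:
        fv, gv, Hv = fgh(s, True)
        fv, gv, Hv = _sanitize(fv, gv, Hv)
    else:
        fv = _sanitize(fgh(s, False)[0])[0]
    lt = logw + z * z + fv - 0.5 * prec * nodes * nodes
    norm = logsumexp(lt, axis=-1)
    logI = norm + _LOG_SQRT2 + np.log(tau) - _LOG_SQRT2PI - np.log(sigma)
    if not need_moments:
        return logI, m, None, None
    with np.errstate(invalid="ignore"):
        wts = np.exp(lt - norm[..., None])
    wts = np.nan_to_num(wts, nan=0.0)
    Eg = np.sum(wts * gv, axis=-1)
    EH = np.sum(wts * Hv, axis=-1)
    Eg2 = np.sum(wts * gv * gv, axis=-1)
    return logI, m, Eg, EH + Eg2 - Eg * Eg


def nested_marginal_loglik(
    fgh,
    eta0: np.ndarray,
    colony_idx: np.ndarray,
    sigma_colony: float,
    sigma_assay: float,
    order: int = 15,
    method: str = "agh",
    cache: dict | None = None,
    return_effects: bool = False,
):
    """Marginal log-likelihood over nested colony/assay Normal random effects.

    ``cache`` (a mutable dict owned by the caller) warm-starts the Newton mode
    searches across nearby parameter values, which is what makes the adaptive
    scheme cheap inside an optimizer loop. With ``return_effects`` the
    posterior modes (``"gh"``: posterior means) of the effects are returned as
    a second value ``(u_per_colony, v_per_row)``.
    """
    eta0 = np.asarray(eta0, dtype=float)
    colony_idx = np.asarray(colony_idx, dtype=int)
    n_colonies = int(colony_idx.max()) + 1 if colony_idx.size else 0
    sc = float(abs(sigma_colony))
    sa = float(abs(sigma_assay))
    if method not in ("agh", "gh"):
        raise ValueError(f"unknown quadrature method {method!r}")
    z, w, logw = gauss_hermite(order)
    logwn = logw - 0.5 * np.log(np.pi)  # weights for int phi(s) f(s) ds
    if cache is None:
        cache = {}
    R = eta0.shape[0]
    u_hat = np.zeros(n_colonies)
    v_hat = np.zeros(R)

    if sa <= SIGMA_ZERO and sc <= SIGMA_ZERO:
        ll = float(np.sum(_sanitize(fgh(eta0, False)[0])[0]))
    elif method == "gh":
        ll, u_hat, v_hat = _plain_gh(fgh, eta0, colony_idx, n_colonies, sc, sa, z, logwn)
    elif sc <= SIGMA_ZERO:
        logI, m, _, _ = _inner_agh(fgh, eta0, sa, z, logw, cache.get("v"))
        cache["v"] = m
        v_hat = m
        ll = float(np.sum(logI))
    elif sa <= SIGMA_ZERO:
        ll, u_hat = _outer_only_agh(fgh, eta0, colony_idx, n_colonies, sc, z, logw, cache)
    else:
        ll, u_hat, v_hat = _nested_agh(fgh, eta0, colony_idx, n_colonies, sc, sa, z, logw, cache)
    if return_effects:
        return ll, (u_hat, v_hat)
    return ll


def _outer_only_agh(fgh, eta0, colony_idx, C, sc, z, logw, cache, max_newton=50, tol=1e-10):
    prec = 1.0 / (sc * sc)
    u = cache.get("u")
    u = np.array(u, dtype=float, copy=True) if (u is not None and np.shape(u) == (C,)) else np.zeros(C)
    Gh = np.full(C, -prec)
    for _ in range(max_newton):
        f, g, H = fgh(eta0 + u[colony_idx], True)
        _, g, H = _sanitize(f, g, H)
        Gg = np.bincount(colony_idx, weights=g, minlength=C) - u * prec
        Gh = np.minimum(np.bincount(colony_idx, weights=H, minlength=C) - prec, -1e-8)
        step = np.clip(-Gg / Gh, -4.0, 4.0)
        u = u + step
        if np.max(np.abs(step)) < tol:
            break
    cache["u"] = u
    tau = 1.0 / np.sqrt(-Gh)
    unodes = u[:, None] + _SQRT2 * tau[:, None] * z
    fgrid = _sanitize(fgh(eta0[:, None] + unodes[colony_idx], False)[0])[0]
    csum = _colony_sum(fgrid, colony_idx, C)
    lt = logw + z * z + csum - 0.5 * prec * unodes * unodes
    ll_c = logsumexp(lt, axis=1) + _LOG_SQRT2 + np.log(tau) - _LOG_SQRT2PI - np.log(sc)
    return float(np.sum(ll_c)), u


def _nested_agh(fgh, eta0, colony_idx, C, sc, sa, z, logw, cache, max_newton=50, tol=1e-9):
    prec = 1.0 / (sc * sc)
    u = cache.get("u")
    u = np.array(u, dtype=float, copy=True) if (u is not None and np.shape(u) == (C,)) else np.zeros(C)
    v0 = cache.get("v")
    Gh = np.full(C, -prec)
    for _ in range(max_newton):
        logI, v0, dI, d2I = _inner_agh(fgh, eta0 + u[colony_idx], sa, z, logw, v0, need_moments=True)
        Gg = np.bincount(colony_idx, weights=dI, minlength=C) - u * prec
        Gh = np.minimum(np.bincount(colony_idx, weights=d2I, minlength=C) - prec, -1e-8)
        step = np.clip(-Gg / Gh, -4.0, 4.0)
        u = u + step
        if np.max(np.abs(step)) < tol:
            break
    tau = 1.0 / np.sqrt(-Gh)
    unodes = u[:, None] + _SQRT2 * tau[:, None] * z  # (C, order)
    logI_grid, m_grid, _, _ = _inner_agh(fgh, eta0[:, None] + unodes[colony_idx], sa, z, logw,
                                         cache.get("v_nodes"))
    csum = _colony_sum(logI_grid, colony_idx, C)
    lt = logw + z * z + csum - 0.5 * prec * unodes * unodes
    ll_c = logsumexp(lt, axis=1) + _LOG_SQRT2 + np.log(tau) - _LOG_SQRT2PI - np.log(sc)
    cache["u"], cache["v"], cache["v_nodes"] = u, v0, m_grid
    return float(np.sum(ll_c)), u, v0


def _plain_gh(fgh, eta0, colony_idx, C, sc, sa, z, logwn):
    """Prior-scaled (non-adaptive) quadrature at both levels."""
    u_hat = np.zeros(C)
    v_hat = np.zeros(eta0.shape[0])
    if sc <= SIGMA_ZERO:  # assay level only
        eta = eta0[:, None] + _SQRT2 * sa * z
        f = _sanitize(fgh(eta, False)[0])[0]
        lt = logwn + f
        inner = logsumexp(lt, axis=1)
        with np.errstate(invalid="ignore"):
            q = np.nan_to_num(np.exp(lt - inner[:, None]), nan=0.0)
        v_hat = q @ (_SQRT2 * sa * z)
        return float(np.sum(inner)), u_hat, v_hat
    if sa <= SIGMA_ZERO:  # colony level only
        eta = eta0[:, None] + _SQRT2 * sc * z
        f = _sanitize(fgh(eta, False)[0])[0]
        csum = _colony_sum(f, colony_idx, C)
        lt = logwn + csum
        ll_c = logsumexp(lt, axis=1)
        with np.errstate(invalid="ignore"):
            p = np.nan_to_num(np.exp(lt - ll_c[:, None]), nan=0.0)
        u_hat = p @ (_SQRT2 * sc * z)
        return float(np.sum(ll_c)), u_hat, v_hat
    eta = eta0[:, None, None] + _SQRT2 * sc * z[None, :, None] + _SQRT2 * sa * z[None, None, :]
    f = _sanitize(fgh(eta, False)[0])[0]
    ilt = logwn + f  # (R, A, B)
    inner = logsumexp(ilt, axis=2)
    csum = _colony_sum(inner, colony_idx, C)
    olt = logwn + csum
    ll_c = logsumexp(olt, axis=1)
    with np.errstate(invalid="ignore"):
        p = np.nan_to_num(np.exp(olt - ll_c[:, None]), nan=0.0)  # (C, A)
        q = np.nan_to_num(np.exp(ilt - inner[..., None]), nan=0.0)  # (R, A, B)
    u_hat = p @ (_SQRT2 * sc * z)
    wr = p[colony_idx][:, :, None] * q
    v_hat = np.sum(wr * (_SQRT2 * sa * z)[None, None, :], axis=(1, 2))
    return float(np.sum(ll_c)), u_hat, v_hat
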