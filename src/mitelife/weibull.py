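"""Mixed-effects interval-censored Weibull time-to-event model.

Development time follows a Weibull distribution with survival

    S(t | i, j) = exp(-(lambda_ij * t)^k),
    log lambda_ij = log lambda0 + beta * x_ij + u_i + v_ij,

where ``k`` is the shape, ``lambda0`` the baseline rate (1/day), ``x_ij`` the
cultivar indicator (1 = Zinfandel), ``u_i ~ N(0, sigma_colony^2)`` a sample
colony effect and ``v_ij ~ N(0, sigma_assay^2)`` an assay-population effect.
An individual observed to mature in the sampling interval ``(t_lo, t_up]``
contributes ``S(t_lo) - S(t_up)``; one never observed as an adult contributes
``S(study_length)``. The marginal likelihood integrates the nested random
effects by (adaptive) Gauss-Hermite quadrature.

The rate acts multiplicatively on the time axis (accelerated-failure-time
convention). The alternative convention ``S(t) = exp(-lambda * t^k)`` is
available as ``parameterization="ph"``; the two differ only by the rescaling
``lambda -> lambda^k`` and by the implied scale of the log-rate effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from ._fitting import fd_hessian, maximize, vcov_from_hessian
from ._marginal import SIGMA_ZERO, nested_marginal_loglik
from .cohorts import IntervalEventData, frame_to_intervals
from .exceptions import DataError, FitError

_LN2 = np.log(2.0)
_EXP_CLIP = 100.0


@dataclass(frozen=True)
class WeibullFrailtyParams:
    """Parameters of the mixed-effects Weibull development-time model."""

    shape: float
    rate0: float
    cultivar_effect: float = 0.0
    sigma_colony: float = 0.0
    sigma_assay: float = 0.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate0 <= 0:
            raise ValueError("shape and rate0 must be positive")
        if self.sigma_colony < 0 or self.sigma_assay < 0:
            raise ValueError("random-effect standard deviations must be non-negative")


def survival_function(t, shape: float, rate: float, parameterization: str = "aft"):
    """P(development time > t) for the Weibull model; vectorized over ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if shape <= 0 or rate <= 0:
        raise ValueError("shape and rate must be positive")
    if parameterization == "aft":
        out = np.exp(-((rate * t) ** shape))
    elif parameterization == "ph":
        out = np.exp(-rate * t ** shape)
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    return out if out.shape else float(out)


def interval_log_likelihood(data: IntervalEventData | None, shape: float, rate: float,
                            parameterization: str = "aft") -> float:
    """Conditional log-likelihood of one assay's interval counts at a given
    rate: the multinomial log-kernel over the interval partition plus the
    right-censored term at the study end. Empty data yields 0."""
    if data is None or (np.size(data.matured) == 0 and data.right_censored == 0):
        return 0.0
    s_lo = survival_function(data.lower, shape, rate, parameterization)
    s_up = survival_function(data.upper, shape, rate, parameterization)
    p = s_lo - s_up
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(np.maximum(p, 0.0))
        terms = np.where(data.matured > 0, data.matured * logp, 0.0)
        terms = np.where(np.isnan(terms), -np.inf, terms)
    ll = float(np.sum(terms))
    if data.right_censored > 0:
        s_end = survival_function(data.study_length, shape, rate, parameterization)
        with np.errstate(divide="ignore"):
            ll += data.right_censored * float(np.log(s_end)) if s_end > 0 else -np.inf
    return ll


def _log1mexp(delta: np.ndarray) -> np.ndarray:
    """log(1 - exp(-delta)) for delta >= 0, stable at both ends."""
    with np.errstate(divide="ignore", invalid="ignore"):
        small = delta < _LN2
        out = np.where(small, np.log(-np.expm1(-np.where(small, delta, 1.0))),
                       np.log1p(-np.exp(-np.where(small, 1.0, delta))))
    return out


class _IntervalArrays:
    """Padded array view of a list of per-assay interval datasets."""

    def __init__(self, dataset: list[IntervalEventData]):
        if not dataset:
            raise DataError("empty interval dataset")
        self.dataset = dataset
        R = len(dataset)
        M = max(d.matured.size for d in dataset)
        self.log_lo = np.zeros((R, M))
        self.log_up = np.full((R, M), _LN2)  # harmless finite pad
        self.counts = np.zeros((R, M))
        self.cens = np.zeros(R)
        self.logT = np.zeros(R)
        with np.errstate(divide="ignore"):
            for r, d in enumerate(dataset):
                m = d.matured.size
                self.log_lo[r, :m] = np.log(d.lower)  # -inf at lower == 0
                self.log_up[r, :m] = np.log(d.upper)
                self.counts[r, :m] = d.matured
                self.cens[r] = d.right_censored
                self.logT[r] = np.log(d.study_length)
        colonies = []
        for d in dataset:
            if d.colony_id not in colonies:
                colonies.append(d.colony_id)
        self.colonies = colonies
        self.colony_idx = np.array([colonies.index(d.colony_id) for d in dataset])
        self.cultivars = [d.cultivar for d in dataset]
        levels = sorted(set(self.cultivars))
        ref = "Zinfandel" if "Zinfandel" in levels else levels[-1]
        self.indicator_level = ref
        self.x = np.array([1.0 if c == ref else 0.0 for c in self.cultivars])
        self.n_matured = int(sum(d.total_matured for d in dataset))
        self.n_censored = int(self.cens.sum())
        self.R, self.M = R, M

    def fgh_builder(self, shape: float, parameterization: str):
        """Conditional log-likelihood of each row as a function of its log-rate
        linear predictor, with analytic first/second derivatives."""
        k = float(shape)
        cs = k if parameterization == "aft" else 1.0
        log_lo, log_up, counts = self.log_lo, self.log_up, self.counts
        cens, logT = self.cens, self.logT
        R, M = self.R, self.M
        has_counts = counts > 0

        def fgh(s, deriv=False):
            nd = s.ndim
            dshape = (R,) + (1,) * (nd - 1) + (M,)
            rshape = (R,) + (1,) * (nd - 1)
            llo = log_lo.reshape(dshape)
            lup = log_up.reshape(dshape)
            cnt = counts.reshape(dshape)
            mask = has_counts.reshape(dshape)
            cn = cens.reshape(rshape)
            lT = logT.reshape(rshape)
            sE = s[..., None]
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                w_lo = np.exp(np.minimum(cs * sE + k * llo, _EXP_CLIP))
                w_up = np.exp(np.minimum(cs * sE + k * lup, _EXP_CLIP))
                delta = np.maximum(w_up - w_lo, 0.0)
                logp = -w_lo + _log1mexp(delta)
                f = np.sum(np.where(mask, cnt * logp, 0.0), axis=-1)
                wT = np.exp(np.minimum(cs * s + k * lT, _EXP_CLIP))
                f = f - cn * wT
                if not deriv:
                    return f, None, None
                em = np.exp(-delta)
                den = np.maximum(-np.expm1(-delta), 1e-300)
                rr = cs * (w_up * em - w_lo) / den
                qq = cs * cs * (w_up * (1.0 - w_up) * em - w_lo * (1.0 - w_lo)) / den
                d2 = qq - rr * rr
                g = np.sum(np.where(mask, cnt * rr, 0.0), axis=-1) - cn * cs * wT
                H = np.sum(np.where(mask, cnt * d2, 0.0), axis=-1) - cn * cs * cs * wT
            return f, g, H

        return fgh


def marginal_log_likelihood(
    params: WeibullFrailtyParams,
    dataset: list[IntervalEventData],
    quadrature_order: int = 15,
    method: str = "agh",
    parameterization: str = "aft",
) -> float:
    """Marginal log-likelihood of the interval dataset, integrating colony and
    assay random effects by nested (adaptive) Gauss-Hermite quadrature. With
    both standard deviations zero this equals the fixed-effects likelihood."""
    arr = _IntervalArrays(dataset)
    eta0 = np.log(params.rate0) + params.cultivar_effect * arr.x
    fgh = arr.fgh_builder(params.shape, parameterization)
    return nested_marginal_loglik(
        fgh, eta0, arr.colony_idx, params.sigma_colony, params.sigma_assay,
        order=quadrature_order, method=method,
    )


class WeibullFrailtyModel(BaseEstimator):
    """Maximum-likelihood estimator for the interval-censored Weibull model
    with nested colony/assay random effects.

    Parameters
    ----------
    model
        ``"cultivar"`` includes the fixed cultivar effect on the log rate,
        ``"null"`` pins it at zero (for likelihood-ratio testing).
    quad_order, quadrature
        Gauss-Hermite order and scheme (``"agh"`` adaptive, ``"gh"`` plain).
    parameterization
        ``"aft"`` for ``exp(-(lambda t)^k)`` (default) or ``"ph"`` for
        ``exp(-lambda t^k)``.
    n_restarts
        Seeded, jittered optimizer restarts after the deterministic two-stage
        warm start.
    compute_vcov
        Whether to assemble the observed-information covariance (variance
        components estimated at the zero boundary are excluded from the
        information matrix and reported with zero rows).

    Attributes (after fit)
    ----------------------
    shape_, rate0_, cultivar_effect_, sigma_colony_, sigma_assay_ : estimates
    loglik_ : maximized marginal log-likelihood
    converged_, boundary_ : diagnostics
    vcov_, param_names_ : covariance on (log shape, log rate0, effect, sds)
    random_effects_ : posterior-mode colony and assay effects
    """

    def __init__(self, model="cultivar", quad_order=15, quadrature="agh",
                 parameterization="aft", n_restarts=2, seed=0, compute_vcov=True,
                 fixed_sigmas=None):
        self.model = model
        self.quad_order = quad_order
        self.quadrature = quadrature
        self.parameterization = parameterization
        self.n_restarts = n_restarts
        self.seed = seed
        self.compute_vcov = compute_vcov
        self.fixed_sigmas = fixed_sigmas

    # -- internals ---------------------------------------------------------
    def _check_inputs(self, X) -> list[IntervalEventData]:
        if isinstance(X, pd.DataFrame):
            X = frame_to_intervals(X)
        if not isinstance(X, (list, tuple)) or not all(isinstance(d, IntervalEventData) for d in X):
            raise TypeError("X must be a list of IntervalEventData or an intervals DataFrame")
        return list(X)

    def _negloglik_factory(self, arr: _IntervalArrays, with_effect: bool):
        cache: dict = {}
        order, method, par = self.quad_order, self.quadrature, self.parameterization

        def negloglik(theta, return_effects=False):
            logk, loglam0 = theta[0], theta[1]
            beta = theta[2] if with_effect else 0.0
            sc, sa = theta[-2], theta[-1]
            fgh = arr.fgh_builder(np.exp(logk), par)
            eta0 = loglam0 + beta * arr.x
            out = nested_marginal_loglik(fgh, eta0, arr.colony_idx, sc, sa,
                                         order=order, method=method, cache=cache,
                                         return_effects=return_effects)
            if return_effects:
                return out
            return -out if np.isfinite(out) else 1e10

        return negloglik

    def fit(self, X, y=None, start=None):
        dataset = self._check_inputs(X)
        arr = _IntervalArrays(dataset)
        if arr.n_matured == 0:
            raise DataError("no individual matured: the time-to-event model is not identifiable")
        with_effect = self.model == "cultivar"
        if with_effect and len(set(arr.cultivars)) < 2:
            raise DataError("cultivar model requires colonies from both cultivars")
        if self.model not in ("cultivar", "null"):
            raise ValueError(f"unknown model {self.model!r}")

        negll = self._negloglik_factory(arr, with_effect)
        p = 4 + int(with_effect)
        if self.fixed_sigmas is not None:
            sc0, sa0 = (float(v) for v in self.fixed_sigmas)
            sigma_bounds = [(sc0, sc0), (sa0, sa0)]
        else:
            sigma_bounds = [(0.0, 3.0)] * 2
        bounds = [(-2.5, 2.5), (-6.0, 3.0)] + ([(-8.0, 8.0)] if with_effect else []) + sigma_bounds

        if start is not None:
            theta0 = np.asarray(start, dtype=float)
            if theta0.size != p:
                raise ValueError(f"start must have length {p}")
            theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        else:
            # stage 1: fixed-effects warm start from a crude moment guess
            mids = 0.5 * (arr.log_lo + arr.log_up)
            with np.errstate(invalid="ignore"):
                tbar = float(np.sum(arr.counts * np.exp(np.where(arr.counts > 0, mids, 0.0)))
                             / max(arr.n_matured, 1))
            tbar = max(tbar, 0.5)
            th_fe = np.concatenate(([np.log(1.5), np.log(0.9027 / tbar)], [0.0] if with_effect else []))
            res_fe = maximize(lambda t: negll(np.concatenate((t, [0.0, 0.0]))), th_fe,
                              bounds[: p - 2], restarts=0, seed=self.seed)
            sig0 = [0.1, 0.1] if self.fixed_sigmas is None else list(self.fixed_sigmas)
            theta0 = np.concatenate((res_fe.x, sig0))

        res = maximize(negll, theta0, bounds, restarts=self.n_restarts, seed=self.seed)
        if not np.isfinite(res.fun):
            raise FitError("Weibull frailty likelihood could not be maximized")
        theta = np.asarray(res.x, dtype=float)

        self.dataset_ = dataset
        self.indicator_level_ = arr.indicator_level
        self.shape_ = float(np.exp(theta[0]))
        self.rate0_ = float(np.exp(theta[1]))
        self.cultivar_effect_ = float(theta[2]) if with_effect else 0.0
        self.sigma_colony_ = float(theta[-2])
        self.sigma_assay_ = float(theta[-1])
        self.loglik_ = float(-res.fun)
        self.converged_ = bool(res.success) and np.isfinite(self.loglik_)
        self.boundary_ = {
            "sigma_colony": self.sigma_colony_ <= 1e-6,
            "sigma_assay": self.sigma_assay_ <= 1e-6,
        }
        self.theta_ = theta
        names = ["log_shape", "log_rate0"] + (["cultivar_effect"] if with_effect else [])
        names += ["sigma_colony", "sigma_assay"]
        self.param_names_ = names
        self.n_obs_ = {
            "n_assays": arr.R,
            "n_colonies": len(arr.colonies),
            "n_matured": arr.n_matured,
            "n_censored": arr.n_censored,
        }
        _, (u_hat, v_hat) = negll(theta, return_effects=True)
        self.random_effects_ = {
            "colony": dict(zip(arr.colonies, (float(u) for u in u_hat))),
            "assay": {d.assay_id: float(v) for d, v in zip(dataset, v_hat)},
        }
        if self.compute_vcov:
            active = [i for i in range(p)
                      if not (i >= p - 2 and (theta[i] <= 1e-6 or self.fixed_sigmas is not None))]
            H = fd_hessian(negll, theta, active=active)
            self.vcov_ = vcov_from_hessian(H, active=active)
        else:
            self.vcov_ = None
        return self

    # -- post-fit API ------------------------------------------------------
    def _require_fitted(self) -> None:
        if not hasattr(self, "loglik_"):
            raise FitError("model is not fitted")

    @property
    def params_(self) -> WeibullFrailtyParams:
        self._require_fitted()
        return WeibullFrailtyParams(self.shape_, self.rate0_, self.cultivar_effect_,
                                    self.sigma_colony_, self.sigma_assay_)

    def rate_for(self, cultivar: str, effect: float = 0.0) -> float:
        """Rate lambda for a cultivar at a given random-effect value."""
        self._require_fitted()
        x = 1.0 if cultivar == self.indicator_level_ else 0.0
        return float(self.rate0_ * np.exp(self.cultivar_effect_ * x + effect))

    def predict_survival(self, t, cultivar: str | None = None, effect: float = 0.0):
        """S(t) at the fitted parameters for the given cultivar (reference
        level when None) and random-effect value."""
        self._require_fitted()
        rate = self.rate_for(cultivar, effect) if cultivar is not None else self.rate0_ * np.exp(effect)
        return survival_function(t, self.shape_, rate, self.parameterization)

    def se(self, name: str) -> float:
        self._require_fitted()
        if self.vcov_ is None:
            raise FitError("fit was run with compute_vcov=False")
        i = self.param_names_.index(name)
        return float(np.sqrt(max(self.vcov_[i, i], 0.0)))


def fit_mle(dataset, model="cultivar", **kwargs) -> WeibullFrailtyModel:
    """Fit the mixed-effects Weibull model by maximum marginal likelihood."""
    return WeibullFrailtyModel(model=model, **kwargs).fit(dataset)


def random_effect_band(fit: WeibullFrailtyModel, q_low: float = 0.05, q_high: float = 0.95,
                       cultivar: str | None = None) -> dict:
    """Extreme fitted curves at quantiles of the combined random effect.

    The colony and assay effects are independent Normals on the log rate, so
    their sum is Normal with variance ``sigma_colony^2 + sigma_assay^2``; the
    band shifts ``log lambda`` by the ``q_low`` and ``q_high`` quantiles of
    that distribution (dashed-curve summary of between-population variation).
    Returns shape plus central/low/high rates.
    """
    if not isinstance(fit, WeibullFrailtyModel) or not hasattr(fit, "loglik_"):
        raise FitError("random_effect_band requires a fitted WeibullFrailtyModel")
    if not 0.0 < q_low <= q_high < 1.0:
        raise ValueError("quantiles must satisfy 0 < q_low <= q_high < 1")
    sigma_tot = float(np.hypot(fit.sigma_colony_, fit.sigma_assay_))
    central = fit.rate_for(cultivar) if cultivar is not None else fit.rate0_
    return {
        "shape": fit.shape_,
        "rate_central": central,
        "rate_low": central * float(np.exp(norm.ppf(q_low) * sigma_tot)),
        "rate_high": central * float(np.exp(norm.ppf(q_high) * sigma_tot)),
        "sigma_total": sigma_tot,
    }


def plot_development_fit(fit: WeibullFrailtyModel, intervals, path=None, q=(0.05, 0.95)):
    """Fitted Weibull densities (central and random-effect band) over the
    per-cultivar histogram of interval-censored maturation counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit._require_fitted()
    colors = {"Zinfandel": "firebrick", "Chardonnay": "seagreen"}
    fig, ax = plt.subplots(figsize=(7, 4.5))
    cultivars = sorted({d.cultivar for d in intervals})
    tgrid = np.linspace(0.0, max(d.study_length for d in intervals), 200)
    for cv in cultivars:
        mids, weights = [], []
        for d in intervals:
            if d.cultivar == cv:
                mids.extend(0.5 * (d.lower + d.upper))
                weights.extend(d.matured)
        color = colors.get(cv, None)
        ax.hist(mids, weights=np.asarray(weights, float), bins=np.arange(0, tgrid[-1] + 2, 2),
                density=True, alpha=0.25, color=color, label=f"{cv} data")
        band = random_effect_band(fit, q[0], q[1], cultivar=cv)
        for rate, style in ((band["rate_central"], "-"), (band["rate_low"], "--"), (band["rate_high"], "--")):
            s = survival_function(tgrid, fit.shape_, rate, fit.parameterization)
            dens = -np.gradient(s, tgrid)
            ax.plot(tgrid, dens, style, color=color)
    ax.set_xlabel("development time (days)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
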