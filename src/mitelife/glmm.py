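"""Binomial and Poisson mixed models with colony and assay random intercepts.

Companion analyses to the time-to-event model:

* day-6 development: binomial, logit link -- probability that a maturing
  individual matured before day 6;
* day-4 survival: binomial, logit link -- probability of surviving to day 4
  out of the founding eggs;
* day-2 fecundity: Poisson, log link -- egg count with the number of
  surviving females on day 2 as a linear fixed covariate.

Each model carries a fixed cultivar effect (indicator 1 = Zinfandel) plus a
colony random intercept and an assay random intercept; since the survival and
fecundity datasets have one record per assay population, the assay effect is
observation-level and doubles as an overdispersion term. The marginal
likelihood over both effects is computed by nested Gauss-Hermite quadrature
(shared engine with the Weibull model), with an analytic gradient on the
plain-quadrature path for fast refitting inside randomization tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit, logsumexp
from sklearn.base import BaseEstimator

from ._fitting import fd_hessian, maximize, vcov_from_hessian
from ._marginal import SIGMA_ZERO, _colony_sum, gauss_hermite, nested_marginal_loglik
from .cohorts import BinaryOutcomeData, FecundityData, binary_to_frame, fecundity_to_frame
from .exceptions import DataError, FitError

logger = logging.getLogger(__name__)

_SQRT2 = np.sqrt(2.0)
_PENALTY_SD = 5.0  # weak Gaussian penalty on coefficients under separation


def _rr(arr: np.ndarray, ndim: int) -> np.ndarray:
    """Reshape a per-row vector for broadcasting against (R, ...) node grids."""
    return arr.reshape((arr.shape[0],) + (1,) * (ndim - 1))


class _NestedGLMM(BaseEstimator):
    """Shared fitting machinery; subclasses define the family and design."""

    def __init__(self, model="cultivar", quad_order=15, quadrature="agh",
                 n_restarts=2, seed=0, compute_vcov=True, fixed_sigmas=None):
        self.model = model
        self.quad_order = quad_order
        self.quadrature = quadrature
        self.n_restarts = n_restarts
        self.seed = seed
        self.compute_vcov = compute_vcov
        self.fixed_sigmas = fixed_sigmas

    # subclass API ---------------------------------------------------------
    def _prepare(self, X) -> pd.DataFrame:  # pragma: no cover - abstract
        raise NotImplementedError

    def _design(self, frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        raise NotImplementedError  # pragma: no cover - abstract

    def _family(self, s: np.ndarray, deriv: bool):
        raise NotImplementedError  # pragma: no cover - abstract

    def _start_coefs(self, Xd: np.ndarray) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover - abstract

    # likelihood -----------------------------------------------------------
    def _loglik_grad_gh(self, theta, Xd, colony_idx, n_colonies):
        """Marginal log-likelihood and analytic gradient, plain prior-scaled
        Gauss-Hermite at both levels."""
        pcoef = Xd.shape[1]
        coefs = theta[:pcoef]
        sc, sa = abs(theta[pcoef]), abs(theta[pcoef + 1])
        eta0 = Xd @ coefs
        z, w, logw = gauss_hermite(self.quad_order)
        logwn = logw - 0.5 * np.log(np.pi)
        if sc <= SIGMA_ZERO and sa <= SIGMA_ZERO:
            f, g, _ = self._family(eta0, True)
            ll = float(np.sum(f))
            dcoef = Xd.T @ g
            dsc = dsa = 0.0
        elif sc <= SIGMA_ZERO:
            eta = eta0[:, None] + _SQRT2 * sa * z
            f, g, _ = self._family(eta, True)
            ilt = logwn + f
            inner = logsumexp(ilt, axis=1)
            ll = float(np.sum(inner))
            gw = np.exp(ilt - inner[:, None]) * g
            dcoef = Xd.T @ gw.sum(axis=1)
            dsc = 0.0
            dsa = _SQRT2 * float(np.sum(gw * z))
        elif sa <= SIGMA_ZERO:
            eta = eta0[:, None] + _SQRT2 * sc * z
            f, g, _ = self._family(eta, True)
            csum = _colony_sum(f, colony_idx, n_colonies)
            olt = logwn + csum
            ll_c = logsumexp(olt, axis=1)
            ll = float(np.sum(ll_c))
            gw = np.exp(olt - ll_c[:, None])[colony_idx] * g
            dcoef = Xd.T @ gw.sum(axis=1)
            dsc = _SQRT2 * float(np.sum(gw * z))
            dsa = 0.0
        else:
            eta = (eta0[:, None, None] + _SQRT2 * sc * z[None, :, None]
                   + _SQRT2 * sa * z[None, None, :])
            f, g, _ = self._family(eta, True)
            ilt = logwn + f  # (R, A, B)
            inner = logsumexp(ilt, axis=2)
            csum = _colony_sum(inner, colony_idx, n_colonies)
            olt = logwn + csum
            ll_c = logsumexp(olt, axis=1)
            ll = float(np.sum(ll_c))
            q = np.exp(ilt - inner[..., None])
            p = np.exp(olt - ll_c[:, None])
            gw = p[colony_idx][:, :, None] * q * g
            dcoef = Xd.T @ gw.sum(axis=(1, 2))
            dsc = _SQRT2 * float(np.sum(gw.sum(axis=2) * z[None, :]))
            dsa = _SQRT2 * float(np.sum(gw * z[None, None, :]))
        grad = np.concatenate((dcoef, [dsc, dsa]))
        if self._penalized:
            ll -= 0.5 * float(np.sum((coefs / _PENALTY_SD) ** 2))
            grad[:pcoef] -= coefs / _PENALTY_SD**2
        return ll, grad

    def _negloglik_factory(self, Xd, colony_idx, n_colonies):
        if self.quadrature == "gh":
            def neg(theta):
                ll, grad = self._loglik_grad_gh(theta, Xd, colony_idx, n_colonies)
                if not np.isfinite(ll):
                    return 1e10, np.zeros_like(theta)
                return -ll, -grad
            return neg, True
        cache: dict = {}
        pcoef = Xd.shape[1]

        def neg(theta):
            coefs = theta[:pcoef]
            ll = nested_marginal_loglik(self._family, Xd @ coefs, colony_idx,
                                        theta[pcoef], theta[pcoef + 1],
                                        order=self.quad_order, method="agh", cache=cache)
            if self._penalized:
                ll -= 0.5 * float(np.sum((coefs / _PENALTY_SD) ** 2))
            return -ll if np.isfinite(ll) else 1e10

        return neg, False

    # fitting --------------------------------------------------------------
    def fit(self, X, y=None, start=None):
        frame = self._prepare(X)
        if self.model not in ("cultivar", "null"):
            raise ValueError(f"unknown model {self.model!r}")
        colonies = list(dict.fromkeys(frame["colony_id"]))
        if len(colonies) < 2:
            raise DataError("mixed model requires at least two colonies")
        if self.model == "cultivar" and frame["cultivar"].nunique() < 2:
            raise DataError("cultivar model requires both cultivar levels")
        colony_idx = np.array([colonies.index(c) for c in frame["colony_id"]])
        Xd, names = self._design(frame)
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            logger.warning("design matrix is rank deficient (constant or collinear "
                           "covariate); coefficients are not separately identifiable")
        self._set_response(frame)
        self._penalized = self._detect_degenerate(frame)

        pcoef = Xd.shape[1]
        neg, has_jac = self._negloglik_factory(Xd, colony_idx, len(colonies))
        if self.fixed_sigmas is not None:
            sc0, sa0 = (float(v) for v in self.fixed_sigmas)
            sigma_bounds = [(sc0, sc0), (sa0, sa0)]
            sig0 = [sc0, sa0]
        else:
            sigma_bounds = [(0.0, 5.0)] * 2
            sig0 = [0.1, 0.1]
        bounds = [(-30.0, 30.0)] * pcoef + sigma_bounds
        if start is not None:
            theta0 = np.asarray(start, dtype=float)
            if theta0.size != pcoef + 2:
                raise ValueError(f"start must have length {pcoef + 2}")
            theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        else:
            theta0 = np.concatenate((self._start_coefs(Xd), sig0))
        res = maximize(neg, theta0, bounds, jac=has_jac or None,
                       restarts=self.n_restarts, seed=self.seed)
        if not np.isfinite(res.fun):
            raise FitError("GLMM likelihood could not be maximized")
        theta = np.asarray(res.x, dtype=float)

        self.frame_ = frame
        self.coef_ = theta[:pcoef].copy()
        self.intercept_ = float(theta[0])
        self.cultivar_effect_ = float(theta[names.index("cultivar_effect")]) if "cultivar_effect" in names else 0.0
        self.sigma_colony_ = float(theta[pcoef])
        self.sigma_assay_ = float(theta[pcoef + 1])
        if has_jac:
            self.loglik_ = float(self._loglik_grad_gh(theta, Xd, colony_idx, len(colonies))[0])
        else:
            self.loglik_ = float(-neg(theta))
        self.converged_ = bool(res.success) and np.isfinite(self.loglik_)
        self.boundary_ = {
            "sigma_colony": self.sigma_colony_ <= 1e-6,
            "sigma_assay": self.sigma_assay_ <= 1e-6,
        }
        self.param_names_ = names + ["sigma_colony", "sigma_assay"]
        self.theta_ = theta
        self.n_obs_ = {"n_rows": int(len(frame)), "n_colonies": len(colonies)}
        _, (u_hat, v_hat) = nested_marginal_loglik(
            self._family, Xd @ self.coef_, colony_idx, self.sigma_colony_, self.sigma_assay_,
            order=self.quad_order, method=self.quadrature, return_effects=True)
        self.random_effects_ = {
            "colony": dict(zip(colonies, (float(u) for u in u_hat))),
            "assay": dict(zip(frame["assay_id"], (float(v) for v in v_hat))),
        }
        if self.compute_vcov:
            fun = (lambda t: neg(t)[0]) if has_jac else neg
            active = [i for i in range(pcoef + 2)
                      if not (i >= pcoef and (theta[i] <= 1e-6 or self.fixed_sigmas is not None))]
            H = fd_hessian(fun, theta, active=active)
            self.vcov_ = vcov_from_hessian(H, active=active)
        else:
            self.vcov_ = None
        return self

    def se(self, name: str) -> float:
        if self.vcov_ is None:
            raise FitError("fit was run with compute_vcov=False")
        i = self.param_names_.index(name)
        return float(np.sqrt(max(self.vcov_[i, i], 0.0)))

    # helpers shared by subclasses ----------------------------------------
    def _cultivar_indicator(self, frame: pd.DataFrame) -> np.ndarray:
        levels = sorted(frame["cultivar"].unique())
        ref = "Zinfandel" if "Zinfandel" in levels else levels[-1]
        self.indicator_level_ = ref
        return (frame["cultivar"] == ref).to_numpy(dtype=float)


class BinomialGLMM(_NestedGLMM):
    """Binomial mixed model (logit link) for successes out of trials per assay
    population, with colony and observation-level assay random intercepts.

    ``logit p_ij = intercept + cultivar_effect * x_ij + u_i + v_ij``

    Zero-trial rows are dropped with a logged warning. Complete separation in
    the aggregated cultivar table raises the ``separation_`` flag and the fit
    falls back to a weakly penalized likelihood (Gaussian penalty, sd 5, on
    the fixed effects).
    """

    def _prepare(self, X) -> pd.DataFrame:
        if isinstance(X, (list, tuple)):
            X = binary_to_frame(list(X))
        frame = X.copy().reset_index(drop=True)
        for col in ("assay_id", "colony_id", "cultivar", "successes", "trials"):
            if col not in frame.columns:
                raise DataError(f"binomial data is missing column {col}")
        n_zero = int((frame["trials"] == 0).sum())
        if n_zero:
            logger.warning("dropping %d zero-trial row(s) from the binomial fit", n_zero)
            frame = frame[frame["trials"] > 0].reset_index(drop=True)
        if frame.empty:
            raise DataError("no rows with trials > 0")
        return frame

    def _design(self, frame: pd.DataFrame):
        cols = [np.ones(len(frame))]
        names = ["intercept"]
        if self.model == "cultivar":
            cols.append(self._cultivar_indicator(frame))
            names.append("cultivar_effect")
        else:
            self._cultivar_indicator(frame)
        return np.column_stack(cols), names

    def _set_response(self, frame: pd.DataFrame) -> None:
        self._succ = frame["successes"].to_numpy(dtype=float)
        self._trials = frame["trials"].to_numpy(dtype=float)
        self._logc = (gammaln(self._trials + 1) - gammaln(self._succ + 1)
                      - gammaln(self._trials - self._succ + 1))

    def _detect_degenerate(self, frame: pd.DataFrame) -> bool:
        groups = frame.groupby("cultivar") if self.model == "cultivar" else [(None, frame)]
        sep = False
        for _, g in groups:
            s, n = g["successes"].sum(), g["trials"].sum()
            if s == 0 or s == n:
                sep = True
        self.separation_ = sep
        if sep:
            logger.warning("complete separation detected; using penalized likelihood")
        return sep

    def _family(self, s, deriv=False):
        succ = _rr(self._succ, s.ndim)
        n = _rr(self._trials, s.ndim)
        f = succ * s - n * np.logaddexp(0.0, s) + _rr(self._logc, s.ndim)
        if not deriv:
            return f, None, None
        mu = expit(s)
        return f, succ - n * mu, -n * mu * (1.0 - mu)

    def _start_coefs(self, Xd: np.ndarray) -> np.ndarray:
        p = (self._succ.sum() + 0.5) / (self._trials.sum() + 1.0)
        out = np.zeros(Xd.shape[1])
        out[0] = logit(p)
        return out

    def predict(self, X) -> np.ndarray:
        """Population-level success probability (random effects at zero)."""
        frame = self._prepare(X)
        Xd, _ = self._design(frame)
        return expit(Xd @ self.coef_)


class PoissonGLMM(_NestedGLMM):
    """Poisson mixed model (log link) for day-2 egg counts.

    ``log mu_ij = intercept + cultivar_effect * x_ij + covariate_effect *
    females_ij + u_i + v_ij``; the observation-level assay intercept doubles
    as an overdispersion term. The surviving-female count enters as a linear
    fixed covariate by default; ``covariate_as_offset=True`` uses
    ``log(females)`` as an offset instead (zero-female rows then contribute
    through the intercept alone).
    """

    def __init__(self, model="cultivar", quad_order=15, quadrature="agh",
                 n_restarts=2, seed=0, compute_vcov=True, fixed_sigmas=None,
                 covariate="surviving_females_day2", covariate_as_offset=False):
        super().__init__(model=model, quad_order=quad_order, quadrature=quadrature,
                         n_restarts=n_restarts, seed=seed, compute_vcov=compute_vcov,
                         fixed_sigmas=fixed_sigmas)
        self.covariate = covariate
        self.covariate_as_offset = covariate_as_offset

    def _prepare(self, X) -> pd.DataFrame:
        if isinstance(X, (list, tuple)):
            X = fecundity_to_frame(list(X))
        frame = X.copy().reset_index(drop=True)
        for col in ("assay_id", "colony_id", "cultivar", "eggs_day2"):
            if col not in frame.columns:
                raise DataError(f"fecundity data is missing column {col}")
        if self.covariate is not None and self.covariate not in frame.columns:
            raise DataError(f"fecundity data is missing column {self.covariate}")
        return frame

    def _design(self, frame: pd.DataFrame):
        cols = [np.ones(len(frame))]
        names = ["intercept"]
        if self.model == "cultivar":
            cols.append(self._cultivar_indicator(frame))
            names.append("cultivar_effect")
        else:
            self._cultivar_indicator(frame)
        self._offset = np.zeros(len(frame))
        if self.covariate is not None:
            cov = frame[self.covariate].to_numpy(dtype=float)
            if self.covariate_as_offset:
                with np.errstate(divide="ignore"):
                    self._offset = np.where(cov > 0, np.log(np.maximum(cov, 1.0)), 0.0)
            else:
                cols.append(cov)
                names.append("covariate_effect")
        return np.column_stack(cols), names

    def _set_response(self, frame: pd.DataFrame) -> None:
        self._y = frame["eggs_day2"].to_numpy(dtype=float)

    def _detect_degenerate(self, frame: pd.DataFrame) -> bool:
        self.all_zero_ = bool((frame["eggs_day2"] == 0).all())
        if self.all_zero_:
            logger.warning("all egg counts are zero; Poisson fit flagged")
        return False

    def _family(self, s, deriv=False):
        y = _rr(self._y, s.ndim)
        off = _rr(self._offset, s.ndim)
        eta = s + off
        mu = np.exp(np.minimum(eta, 50.0))
        f = y * eta - mu - _rr(gammaln(self._y + 1), s.ndim)
        if not deriv:
            return f, None, None
        return f, y - mu, -mu

    def _start_coefs(self, Xd: np.ndarray) -> np.ndarray:
        out = np.zeros(Xd.shape[1])
        out[0] = np.log(self._y.mean() + 0.5) - float(np.mean(self._offset))
        return out

    @property
    def covariate_effect_(self) -> float:
        if "covariate_effect" in self.param_names_:
            return float(self.theta_[self.param_names_.index("covariate_effect")])
        return 0.0

    def predict(self, X) -> np.ndarray:
        """Population-level expected count (random effects at zero)."""
        frame = self._prepare(X)
        Xd, _ = self._design(frame)
        return np.exp(Xd @ self.coef_ + self._offset)


def fit_binomial_glmm(data, model: str = "cultivar", **kwargs) -> BinomialGLMM:
    """Fit the binomial mixed model to a list of per-assay success/trial
    records (or an equivalent DataFrame)."""
    return BinomialGLMM(model=model, **kwargs).fit(data)


def fit_poisson_glmm(data, model: str = "cultivar", **kwargs) -> PoissonGLMM:
    """Fit the Poisson fecundity mixed model."""
    return PoissonGLMM(model=model, **kwargs).fit(data)
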