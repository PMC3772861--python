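"""Interval-censored Weibull frailty model: closed forms, oracles, and fits."""

import numpy as np
import pytest
from scipy import optimize, stats

import mitelife as ml
from mitelife.cohorts import IntervalEventData
from mitelife.exceptions import DataError, FitError
from mitelife.weibull import (WeibullFrailtyParams, interval_log_likelihood,
                              marginal_log_likelihood, random_effect_band,
                              survival_function)


def test_survival_function_closed_forms():
    assert survival_function(1.0, 1.0, np.log(2.0)) == pytest.approx(0.5, abs=1e-12)
    assert survival_function(2.0, 2.0, 0.5) == pytest.approx(np.exp(-1.0), abs=1e-12)
    assert survival_function(0.0, 3.7, 0.9) == 1.0
    # the two parameterizations coincide after rate -> rate^k rescaling
    assert survival_function(3.0, 2.0, 0.25, "ph") == pytest.approx(
        survival_function(3.0, 2.0, 0.5, "aft"), abs=1e-12)
    with pytest.raises(ValueError):
        survival_function(-1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        survival_function(1.0, 0.0, 1.0)


def test_interval_loglik_exponential_half_life():
    d = IntervalEventData("a", "c", "Zinfandel", [0.0], [1.0], [1], 0, 1)
    assert interval_log_likelihood(d, 1.0, np.log(2.0)) == pytest.approx(np.log(0.5), abs=1e-12)


def test_interval_loglik_is_multinomial_kernel():
    """On a full partition the interval probabilities plus the censored mass
    sum to one, and the log-likelihood is the multinomial log-kernel."""
    k, lam = 2.0, 0.18
    d = IntervalEventData("a", "c", "Zinfandel", [0, 2, 4], [2, 4, 6], [2, 4, 1], 3, 10)
    edges = np.array([0.0, 2.0, 4.0, 6.0])
    probs = survival_function(edges[:-1], k, lam) - survival_function(edges[1:], k, lam)
    p_all = np.append(probs, survival_function(6.0, k, lam))
    counts = np.array([2, 4, 1, 3])
    assert p_all.sum() == pytest.approx(1.0, abs=1e-12)
    from scipy.special import gammaln
    log_coef = gammaln(11) - gammaln(counts + 1).sum()
    expected = stats.multinomial.logpmf(counts, 10, p_all) - log_coef
    assert interval_log_likelihood(d, k, lam) == pytest.approx(expected, abs=1e-10)


def test_interval_loglik_empty_and_impossible():
    assert interval_log_likelihood(None, 2.0, 0.2) == 0.0
    d = IntervalEventData("a", "c", "Zinfandel", [0.0], [1e-12 + 0.001], [1], 0, 1)
    # a vanishing interval probability with a nonzero count drives ll to -inf
    assert interval_log_likelihood(d, 8.0, 1e-6) < -1e2


def test_fixed_effects_mle_matches_lifelines_and_grid(tte_oracle_data):
    """With both variance components pinned at zero the fit agrees with the
    independent interval-censoring fitter from lifelines and with a direct
    optimization of the likelihood from a separate starting point."""
    from lifelines import WeibullFitter

    intervals = tte_oracle_data
    fit = ml.WeibullFrailtyModel(model="null", fixed_sigmas=(0.0, 0.0)).fit(intervals)
    lo, up = [], []
    for d in intervals:
        for l, u, m in zip(d.lower, d.upper, d.matured):
            lo += [l] * int(m)
            up += [u] * int(m)
        lo += [d.study_length] * d.right_censored
        up += [np.inf] * d.right_censored
    lf = WeibullFitter().fit_interval_censoring(np.maximum(lo, 1e-9), up)
    assert fit.shape_ == pytest.approx(lf.rho_, rel=1e-3)
    assert fit.rate0_ == pytest.approx(1.0 / lf.lambda_, rel=1e-3)

    def nll(theta):
        return -marginal_log_likelihood(
            WeibullFrailtyParams(np.exp(theta[0]), np.exp(theta[1])), intervals, 15)

    res = optimize.minimize(nll, [0.0, -1.0], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12})
    assert fit.shape_ == pytest.approx(np.exp(res.x[0]), rel=1e-3)
    assert fit.rate0_ == pytest.approx(np.exp(res.x[1]), rel=1e-3)
    assert fit.loglik_ == pytest.approx(-res.fun, abs=1e-6)


@pytest.fixture(scope="module")
def tte_oracle_data():
    design = ml.ExperimentDesign(colonies=tuple((f"Z{i}", "Zinfandel") for i in range(4)),
                                 egg_cohort_size=50)
    cfg = ml.GeneratorConfig(design=design, seed=5, sigma_assay=0.0, sigma_colony=0.0,
                             cultivar_effect=0.0, survival_zinfandel=1.0,
                             survival_chardonnay=1.0)
    return ml.derive_analysis_datasets(ml.simulate_experiment(cfg))["intervals"]


def test_exponential_special_case_matches_lifelines(tte_oracle_data):
    """Pinning the shape near one reduces the model to interval-censored
    exponential survival; compare against lifelines' exponential fitter."""
    from lifelines import ExponentialFitter

    intervals = tte_oracle_data
    lo, up = [], []
    for d in intervals:
        for l, u, m in zip(d.lower, d.upper, d.matured):
            lo += [l] * int(m)
            up += [u] * int(m)
        lo += [d.study_length] * d.right_censored
        up += [np.inf] * d.right_censored
    ef = ExponentialFitter().fit_interval_censoring(np.maximum(lo, 1e-9), up)

    def nll(loglam):
        return -marginal_log_likelihood(
            WeibullFrailtyParams(1.0, np.exp(loglam[0])), intervals, 15)

    res = optimize.minimize_scalar(lambda x: nll([x]), bounds=(-4, 1), method="bounded",
                                   options={"xatol": 1e-10})
    assert np.exp(res.x) == pytest.approx(1.0 / ef.lambda_, rel=1e-4)


def test_full_fit_diagnostics(tte_fits, derived):
    full, null = tte_fits
    assert full.converged_ and null.converged_
    assert full.loglik_ >= null.loglik_ - 1e-6
    assert full.shape_ > 0 and full.rate0_ > 0
    V = full.vcov_
    np.testing.assert_allclose(V, V.T, atol=1e-12)
    active = [i for i, n in enumerate(full.param_names_)
              if not (n.startswith("sigma") and full.boundary_[n])]
    eig = np.linalg.eigvalsh(V[np.ix_(active, active)])
    assert np.all(eig > -1e-10)
    assert set(full.random_effects_["assay"]) == {d.assay_id for d in derived["intervals"]}
    # sklearn-style parameter plumbing
    assert full.get_params()["quad_order"] == 15


def test_degenerate_inputs_raise(derived):
    censored = [IntervalEventData("a1", "c1", "Zinfandel", [0, 2], [2, 4], [0, 0], 10, 10),
                IntervalEventData("a2", "c2", "Chardonnay", [0, 2], [2, 4], [0, 0], 10, 10)]
    with pytest.raises(DataError, match="matured"):
        ml.fit_mle(censored)
    one_level = [d for d in derived["intervals"] if d.cultivar == "Zinfandel"]
    with pytest.raises(DataError, match="both cultivars"):
        ml.fit_mle(one_level, model="cultivar")


def test_random_effect_band_quantile_shifts(tte_fits):
    full, _ = tte_fits
    band = random_effect_band(full, 0.05, 0.95, cultivar="Zinfandel")
    sigma_tot = np.hypot(full.sigma_colony_, full.sigma_assay_)
    central = full.rate_for("Zinfandel")
    assert band["rate_low"] == pytest.approx(central * np.exp(-1.6449 * sigma_tot), rel=1e-4)
    assert band["rate_high"] == pytest.approx(central * np.exp(1.6449 * sigma_tot), rel=1e-4)
    # bands bracket the central curve pointwise (rate is monotone in survival)
    t = np.linspace(0.1, 12, 30)
    s_c = survival_function(t, band["shape"], band["rate_central"])
    s_lo = survival_function(t, band["shape"], band["rate_low"])
    s_hi = survival_function(t, band["shape"], band["rate_high"])
    assert np.all(s_lo >= s_c - 1e-12) and np.all(s_hi <= s_c + 1e-12)


def test_random_effect_band_degenerate_and_errors(toy_intervals):
    fit = ml.WeibullFrailtyModel(model="cultivar", fixed_sigmas=(0.0, 0.0),
                                 n_restarts=0).fit(toy_intervals)
    band = random_effect_band(fit)
    assert band["rate_low"] == band["rate_central"] == band["rate_high"]
    with pytest.raises(FitError):
        random_effect_band(ml.WeibullFrailtyModel())


def test_parameterization_flag_reaches_same_maximum(toy_intervals):
    """The two rate conventions describe the same family at sigma = 0, so the
    maximized likelihood agrees and the rates map as lambda_aft^k."""
    aft = ml.WeibullFrailtyModel(model="null", fixed_sigmas=(0.0, 0.0),
                                 parameterization="aft", n_restarts=1).fit(toy_intervals)
    ph = ml.WeibullFrailtyModel(model="null", fixed_sigmas=(0.0, 0.0),
                                parameterization="ph", n_restarts=1).fit(toy_intervals)
    assert aft.loglik_ == pytest.approx(ph.loglik_, abs=1e-6)
    assert ph.rate0_ == pytest.approx(aft.rate0_ ** aft.shape_, rel=1e-3)
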