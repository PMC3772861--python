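"""Binomial and Poisson mixed models: GLM oracles, gradients, and recovery."""

import logging

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit, logsumexp

import mitelife as ml
from mitelife.cohorts import binary_to_frame, fecundity_to_frame
from mitelife.exceptions import DataError
from mitelife.glmm import BinomialGLMM, PoissonGLMM


@pytest.fixture(scope="module")
def glmm_data():
    cfg = ml.GeneratorConfig(seed=11, female_day2_survival=0.9)
    ds = ml.derive_analysis_datasets(ml.simulate_experiment(cfg))
    return {
        "survival": binary_to_frame(ds["survival"]),
        "day6": binary_to_frame(ds["day6"]),
        "fecundity": fecundity_to_frame(ds["fecundity"]),
    }


@pytest.mark.parametrize("quadrature", ["gh", "agh"])
def test_binomial_sigma_zero_equals_glm(glmm_data, quadrature):
    df = glmm_data["survival"]
    fit = BinomialGLMM(fixed_sigmas=(0.0, 0.0), quadrature=quadrature).fit(df)
    x = (df.cultivar == "Zinfandel").astype(float).to_numpy()
    glm = sm.GLM(np.column_stack([df.successes, df.trials - df.successes]),
                 sm.add_constant(x), family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.coef_, glm.params, atol=1e-6)
    assert fit.loglik_ == pytest.approx(glm.llf, abs=1e-8)


def test_poisson_sigma_zero_equals_glm(glmm_data):
    df = glmm_data["fecundity"]
    fit = PoissonGLMM(fixed_sigmas=(0.0, 0.0), quadrature="gh").fit(df)
    X = np.column_stack([np.ones(len(df)), (df.cultivar == "Zinfandel").astype(float),
                         df.surviving_females_day2])
    glm = sm.GLM(df.eggs_day2, X, family=sm.families.Poisson()).fit()
    np.testing.assert_allclose(fit.coef_, glm.params, atol=1e-6)
    assert fit.loglik_ == pytest.approx(glm.llf, abs=1e-8)


def test_poisson_scale_invariance(glmm_data):
    """Scaling every count by an integer factor shifts the intercept by log c
    and leaves the other coefficients unchanged (offset-free invariance)."""
    df = glmm_data["fecundity"]
    scaled = df.assign(eggs_day2=3 * df.eggs_day2)
    a = PoissonGLMM(fixed_sigmas=(0.0, 0.0), quadrature="gh").fit(df)
    b = PoissonGLMM(fixed_sigmas=(0.0, 0.0), quadrature="gh").fit(scaled)
    assert b.intercept_ - a.intercept_ == pytest.approx(np.log(3.0), abs=1e-5)
    np.testing.assert_allclose(a.coef_[1:], b.coef_[1:], atol=1e-5)


def test_glmm_gradient_matches_finite_differences(glmm_data):
    m = BinomialGLMM(model="cultivar", quadrature="gh", quad_order=11)
    fr = m._prepare(glmm_data["day6"])
    colonies = list(dict.fromkeys(fr["colony_id"]))
    cidx = np.array([colonies.index(c) for c in fr["colony_id"]])
    Xd, _ = m._design(fr)
    m._set_response(fr)
    m._penalized = False
    theta = np.array([0.4, -0.2, 0.3, 0.25])
    _, g = m._loglik_grad_gh(theta, Xd, cidx, len(colonies))
    for i in range(4):
        e = np.zeros(4)
        e[i] = 1e-6
        fd = (m._loglik_grad_gh(theta + e, Xd, cidx, len(colonies))[0]
              - m._loglik_grad_gh(theta - e, Xd, cidx, len(colonies))[0]) / 2e-6
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_agh_matches_monte_carlo_on_small_toy():
    """Marginal likelihood against nested Monte-Carlo integration on a
    three-colony binomial toy, within 0.5% of |loglik|."""
    df = pd.DataFrame({
        "assay_id": [f"a{i}" for i in range(6)],
        "colony_id": ["c1", "c1", "c2", "c2", "c3", "c3"],
        "cultivar": ["Zinfandel"] * 4 + ["Chardonnay"] * 2,
        "successes": [3, 5, 7, 2, 4, 6],
        "trials": [8, 9, 10, 7, 8, 10],
    })
    theta = np.array([0.2, 0.3, 0.35, 0.45])
    m = BinomialGLMM(model="cultivar", quadrature="gh", quad_order=25)
    fr = m._prepare(df)
    colonies = list(dict.fromkeys(fr["colony_id"]))
    cidx = np.array([colonies.index(c) for c in fr["colony_id"]])
    Xd, _ = m._design(fr)
    m._set_response(fr)
    m._penalized = False
    ll, _ = m._loglik_grad_gh(theta, Xd, cidx, len(colonies))

    rng = np.random.default_rng(7)
    N, M = 1000, 400
    eta0 = Xd @ theta[:2]
    succ = fr.successes.to_numpy()
    tri = fr.trials.to_numpy()
    from scipy.special import gammaln
    logc = gammaln(tri + 1) - gammaln(succ + 1) - gammaln(tri - succ + 1)
    mc = 0.0
    for c in range(3):
        rows = np.where(cidx == c)[0]
        u = theta[2] * rng.standard_normal(N)
        tot = np.zeros(N)
        for r in rows:
            v = theta[3] * rng.standard_normal((N, M))
            eta = eta0[r] + u[:, None] + v
            f = succ[r] * eta - tri[r] * np.logaddexp(0, eta) + logc[r]
            tot += logsumexp(f, axis=1) - np.log(M)
        mc += float(logsumexp(tot) - np.log(N))
    assert abs(ll - mc) <= 0.005 * abs(mc)


def test_separation_flag_and_penalized_fallback(caplog):
    df = pd.DataFrame({
        "assay_id": list("abcdef"),
        "colony_id": ["c1", "c1", "c2", "c2", "c3", "c3"],
        "cultivar": ["Zinfandel"] * 4 + ["Chardonnay"] * 2,
        "successes": [8, 9, 10, 7, 4, 6],  # Zinfandel all successes
        "trials": [8, 9, 10, 7, 8, 10],
    })
    with caplog.at_level(logging.WARNING, logger="mitelife.glmm"):
        fit = BinomialGLMM(model="cultivar", quadrature="gh", n_restarts=0).fit(df)
    assert fit.separation_
    assert np.isfinite(fit.loglik_) and abs(fit.cultivar_effect_) < 25


def test_zero_trial_rows_are_excluded(glmm_data):
    df = glmm_data["day6"]
    extra = pd.concat([df, pd.DataFrame([{
        "assay_id": "zz", "colony_id": df.colony_id.iloc[0],
        "cultivar": df.cultivar.iloc[0], "successes": 0, "trials": 0}])],
        ignore_index=True)
    a = BinomialGLMM(quadrature="gh", n_restarts=0).fit(df)
    b = BinomialGLMM(quadrature="gh", n_restarts=0).fit(extra)
    assert b.loglik_ == pytest.approx(a.loglik_, abs=1e-8)
    assert b.n_obs_["n_rows"] == a.n_obs_["n_rows"]


def test_requires_two_colonies_and_two_levels(glmm_data):
    df = glmm_data["survival"]
    with pytest.raises(DataError, match="two colonies"):
        BinomialGLMM().fit(df[df.colony_id == df.colony_id.iloc[0]])
    with pytest.raises(DataError, match="cultivar"):
        BinomialGLMM(model="cultivar").fit(df[df.cultivar == "Zinfandel"])


def test_survival_effect_recovery_across_replicates():
    """Simulated at the survival defaults 0.767 / 0.633 the cultivar effect on
    the logit scale is about 0.646; the average estimate over replicates
    should recover it within simulation error."""
    true_beta = float(np.log(0.767 / 0.233) - np.log(0.633 / 0.367))
    est = []
    for rep in range(30):
        cfg = ml.GeneratorConfig(seed=700 + rep, survival_sigma_assay=0.0)
        surv = binary_to_frame(ml.derive_analysis_datasets(
            ml.simulate_experiment(cfg))["survival"])
        est.append(BinomialGLMM(quadrature="gh", n_restarts=0,
                                compute_vcov=False).fit(surv).cultivar_effect_)
    est = np.asarray(est)
    assert est.mean() == pytest.approx(true_beta, abs=3.5 * est.std(ddof=1) / np.sqrt(est.size))


def test_fecundity_null_effect_is_centred():
    est = []
    for rep in range(30):
        cfg = ml.GeneratorConfig(seed=800 + rep, female_day2_survival=0.9)
        fec = fecundity_to_frame(ml.derive_analysis_datasets(
            ml.simulate_experiment(cfg))["fecundity"])
        est.append(PoissonGLMM(quadrature="gh", n_restarts=0,
                               compute_vcov=False).fit(fec).cultivar_effect_)
    est = np.asarray(est)
    assert abs(est.mean()) <= 3.5 * est.std(ddof=1) / np.sqrt(est.size)


def test_predict_returns_population_means(glmm_data):
    fit = BinomialGLMM(quadrature="gh", n_restarts=0).fit(glmm_data["survival"])
    p = fit.predict(glmm_data["survival"])
    np.testing.assert_allclose(
        p, expit(fit.intercept_ + fit.cultivar_effect_
                 * (glmm_data["survival"].cultivar == "Zinfandel")), atol=1e-12)
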