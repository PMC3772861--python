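# mitelife

Life-history analysis of spider-mite cohort assays: interval-censored Weibull
time-to-event models with nested random effects, binomial and Poisson GLMMs,
and randomization likelihood-ratio tests — plus a synthetic-data generator
that reproduces the hierarchical common-garden design, so the whole pipeline
runs with no external data.

## The problem

Pacific spider mites (*Tetranychus pacificus*) collected from vineyards
growing different grape cultivars (Zinfandel vs Chardonnay) are reared in a
common garden on bean plants. Each field-derived **sample colony** founds
four **assay populations**: two cohorts of 10 eggs and two cohorts of 5 mated
females, each photographed every 48 h for 12 days. The question is whether
lines from different source cultivars differ in three life-history traits:
juvenile development time, juvenile survival, and early fecundity.

The photographic design means development times are **interval-censored**
(an individual first seen as an adult on day *d* matured somewhere in
(*d* − 2, *d*]) and the sampling hierarchy (cultivar → colony → assay
population) induces shared random variation at two levels. This package is
for quantitative ecologists who need to fit exactly that structure: a
parametric time-to-event model with nested frailties on grouped,
interval-censored count data, with companion GLMMs and permutation-based
inference for small numbers of groups.

## Models

**Development (time-to-event).** Individual maturation time in assay *j* of
colony *i* follows a Weibull distribution with survival function

    S(t | i, j) = exp( −(λ_ij · t)^k ),
    log λ_ij = log λ₀ + β·x_ij + u_i + v_ij,
    u_i ~ N(0, σ²_colony),   v_ij ~ N(0, σ²_assay),

where *k* is the shape, λ₀ the baseline rate (day⁻¹), and *x_ij* = 1 for
Zinfandel-sourced lines, so β > 0 means faster development on Zinfandel. An
individual maturing in (t₁, t₂] contributes S(t₁) − S(t₂); one never seen as
an adult contributes S(12). The marginal likelihood integrates both random
effects by nested adaptive Gauss–Hermite quadrature, and σ̂ = 0 boundary
estimates are representable exactly.

**Survival and fecundity (GLMMs).** The probability of maturing before day 6
(among maturers) and of surviving to day 4 (out of 10 eggs) are binomial
logit models; day-2 egg counts are a Poisson log model with the number of
surviving females as a fixed covariate. All carry the cultivar fixed effect
plus colony and assay random intercepts (the assay intercept is
observation-level and doubles as an overdispersion term).

**Inference.** Each analysis compares models with and without the cultivar
effect via the likelihood-ratio statistic D = 2·Δlog L, with p-values from
(a) the chi-squared approximation and (b) a randomization distribution built
by permuting cultivar labels across whole sample colonies and refitting both
models per permutation — the honest option when there are only 11 colonies.
An exhaustive mode enumerates all C(11, 3) = 165 assignments for an exact
test.

## Worked example

```python
import mitelife as ml

cfg = ml.GeneratorConfig(seed=1)            # study design + generator defaults
series = ml.simulate_experiment(cfg)        # 44 photographed count series
datasets = ml.derive_analysis_datasets(series)

fit = ml.fit_mle(datasets["intervals"])     # mixed-effects Weibull, cultivar model
null = ml.fit_mle(datasets["intervals"], model="null")
D, p = ml.lrt(fit, null)
```

printing the fitted development model:

```
assay populations: 44 (22 egg-initiated)
shape k = 1.016, baseline rate lambda0 = 0.1105/day
cultivar effect beta = 0.213 (log-rate scale, Zinfandel = 1)
sigma_colony = 0.0000, sigma_assay = 0.4771
development LRT: D = 0.531, chi-squared p = 0.466
```

The colony variance sits exactly on the zero boundary while assay
populations vary — colonies tell you nothing beyond their assays here — and
the positive β points to faster development in Zinfandel lines, though this
single simulated experiment is not significant. Note the fitted shape is
pulled toward 1 because non-survivors are right-censored at day 12 (see
`docs/methods.md` on the censoring policy). The randomization test for the
day-6 development GLMM:

```python
from mitelife.glmm import BinomialGLMM
from mitelife.pipeline import glmm_lrt_fitter
day6 = ml.cohorts.binary_to_frame(datasets["day6"])
res = ml.randomization_test(day6[day6.trials > 0],
                            glmm_lrt_fitter(BinomialGLMM), n_perm=999, seed=1)
```

```
day-6 GLMM: D = 0.961, randomization p = 0.348 (999 permutations)
```

The same pipeline is available from the shell:

```bash
mitelife run-all --seed 1 --out-dir results/
mitelife generate --seed 1 --out counts.csv
mitelife derive --counts counts.csv --out-dir derived/
mitelife fit-tte --intervals derived/intervals.csv --out fit.json
mitelife test --analysis day6 --data derived/day6.csv --n-perm 1000 --out test.json
```

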