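# Methods

## Data model and derivations

Raw data are long-format stage counts: for every assay population and every
sampling day (0, 2, …, 12), the number of eggs, immatures and adults counted
in the photographs. Three analysis datasets are derived:

**Maturation intervals.** For egg cohorts, the count maturing in
(d − 2, d] is the positive increment of the adult count above its running
maximum. The running-max rule is a deliberate completion of the counting
protocol: adult counts can dip when an adult dies, and a naive
first-difference would then count the same maturation twice when the count
recovers. Individuals never observed as adults by day 12 — both slow
developers and juveniles that died — are treated as right-censored at day 12
(`censoring="censor-nonmatured"`). Individual deaths are not observable in
stage counts, so a censor-at-death policy is impossible; the alternative
`"drop-nonmatured"` removes non-maturers from the risk set entirely.
Consequence of the default: when juvenile mortality is substantial, the
censored mass at day 12 is partly mis-attributed to slow development, which
drags the fitted Weibull shape toward 1 and the rate downward. This is a
property of the estimand, not a numerical artifact; it is why the
parameter-recovery study (below) switches mortality off.

**Day-6 dichotomy.** Maturations are split into before/after day 6, with an
observation first seen on day 6 counted as early (intervals with upper
bound ≤ 6). Trials default to the individuals that matured at any point
during the study — the dichotomy partitions maturers, not the founding
cohort — with `denominator="initial"` available. Zero-trial records are kept
in the dataset but dropped (with a logged warning) by the binomial fit.

**Day-4 survival.** Survivors are all individuals present in the day-4
photograph (eggs + immatures + adults, capped at 10) out of the founding 10
eggs. Day 4 is early enough that maturation has essentially not begun, so
presence is an honest proxy for juvenile survival.

**Day-2 fecundity.** The day-2 egg count of each adult cohort, with the
number of females alive on day 2 as a covariate for adult mortality.

## The time-to-event model

Weibull survival S(t) = exp(−(λt)^k) with effects on log λ
(accelerated-failure-time convention): log λ_ij = log λ₀ + β·x + u_i + v_ij
with independent Normal colony and assay effects. The alternative
convention S(t) = exp(−λ t^k) differs only by the reparameterization
λ → λ^k and is exposed as `parameterization="ph"`.

The per-assay conditional likelihood is the multinomial kernel over the
interval partition plus the right-censored term S(12). Interval
probabilities are computed as exp(−w_lo)·(1 − exp(−Δ)) with Δ = w_up − w_lo
in log space (`log1mexp`), and the first two derivatives with respect to the
log-rate are analytic — these drive both the quadrature adaptation and the
GLMM gradient path.

**Marginalization.** The nested integral (colony outer, assay inner) is
evaluated by Gauss–Hermite quadrature, default adaptive (`"agh"`, order 15):
each integrand is re-centred and re-scaled at its conditional mode, found by
damped Newton with the analytic derivatives; outer-level derivatives of the
inner integrals are posterior moments of f′ and f″ under the inner
quadrature weights. Mode searches warm-start from the previous likelihood
evaluation, which makes the adaptive scheme cheap inside an optimizer. A
plain prior-scaled scheme (`"gh"`) is also provided; it admits a fully
analytic gradient for the GLMMs and is used for the thousands of refits
inside randomization tests (order 9 there — on these problem sizes it agrees
with the adaptive order-15 likelihood to ~1e-4). Order 1 of the adaptive
scheme is the Laplace approximation. Accuracy checks: against
scipy.integrate on toys, against 10⁶-draw nested Monte-Carlo integration,
and monotone convergence in the order.

**Optimization.** L-BFGS-B on (log k, log λ₀, β, σ_colony, σ_assay) with
σ ≥ 0 bounds on the standard-deviation scale, so boundary estimates σ̂ = 0
are exact — the zero colony variance is a genuine, expected outcome, not a
numerical failure. Bounds: log k ∈ [−2.5, 2.5], log λ₀ ∈ [−6, 3],
β ∈ [−8, 8], σ ∈ [0, 3]. The fit is two-stage: a fixed-effects fit (σ = 0)
from a moment-based start, then the full model from that solution with
σ started at 0.1, plus (by default) two seeded jittered restarts; the warm
start made a larger pure multi-start redundant in pilot runs. Convergence
tolerance is 1e-12 relative on the objective. A caveat that follows from the
likelihood being an even function of each σ: the gradient in σ vanishes at
zero, so escaping a spurious boundary solution relies on the interior start
and the restarts.

**Uncertainty.** The observed information is a central finite-difference
Hessian on the working scale; variance components estimated at the boundary
are excluded from the information matrix (their rows of the covariance are
zero) and flagged in `boundary_`. Predicted random effects are the
posterior modes at the MLE. The quantile band summarising between-population
variation shifts log λ by Normal quantiles of the combined effect
N(0, σ²_colony + σ²_assay).

## GLMMs

Binomial (logit) and Poisson (log) mixed models with the same nested
intercepts and the same quadrature/optimizer machinery. For the survival and
fecundity datasets there is one record per assay, so the assay intercept is
observation-level; in the Poisson model it acts as a log-normal
overdispersion term, and σ̂_assay = 0 is common. The surviving-female count
enters as a linear fixed covariate (an offset option exists). When all
females survive the covariate is constant and collinear with the intercept;
the fit warns that the two are not separately identifiable (the likelihood,
and hence every LRT, is unaffected). Complete separation in the aggregated
cultivar table raises a flag and falls back to a weak Gaussian penalty
(sd 5) on the fixed effects.

## Likelihood-ratio inference

D = 2(log L_full − log L_null) with p-values from χ²₁ and from
randomization: cultivar labels are permuted across whole sample colonies
(labels travel with all four of a colony's assay populations), preserving
the 8/3 split, and both models are refitted per permutation with random
effects re-estimated. The permutation unit is the colony because that is
the level at which the cultivar label attaches to independent units;
assay-level permutation is available for sensitivity analysis. The sampled
p-value is (1 + #{D_perm ≥ D_obs})/(n + 1); exhaustive enumeration of the
165 distinct assignments gives the exact p. Permutations use per-index
seeded substreams, identical assignments are fitted once, and the null fit
— which does not involve the labels — is computed once per dataset. All
full fits, observed and permuted alike, start from the null solution with
β inserted at 0: a symmetric optimization policy across relabellings, which
matters because any systematic asymmetry in optimizer quality would bias
the randomization p-value.

## Synthetic experiments

The generator reproduces the study conditions: 11 colonies (8 Zinfandel,
3 Chardonnay), 2 egg cohorts of 10 and 2 adult cohorts of 5 per colony,
sampled every 2 days for 12 days. Defaults: development k = 2.5,
λ₀ = 0.2/day, β = 0.3, σ_assay = 0.2, σ_colony = 0 (moderate assay
variation, none between colonies, Zinfandel faster — the qualitative
finding of the study; mean development ≈ 3.3 days for Zinfandel and 4.4 for
Chardonnay lines); juvenile survival 0.767 / 0.633 (Zinfandel / Chardonnay);
fecundity 10.8 eggs per female per 2 days. Survival and fecundity
heterogeneity scales are not pinned down by any reported quantity; they
were set once to plausible magnitudes relative to the development model —
logit-scale σ_assay = 0.3 (assay-level survival roughly ±6 percentage
points), log-scale σ_assay = 0.15 (±15% fecundity), both with σ_colony = 0.

Mechanics: egg-cohort development times are Weibull draws thinned by a
single Bernoulli survival per individual; non-survivors never appear as
adults and die at a uniform time before day 4 (this placement only shapes
intermediate stage counts, which no analysis uses). Survivors' maturations
are binned to the first sampling day ≥ the event. Egg hatching is rendered
deterministically after a 2-day egg stage — a cosmetic stage split. Adult
cohorts lay Poisson eggs per surviving female per interval, extended past
day 2 only to fill the series. Every assay and colony draws from its own
substream keyed by a stable hash of its id under one root seed, so
extending the design never perturbs existing series.

What the generator does **not** emulate: temperature effects, egg-stage
mortality distinct from juvenile mortality, adult deaths in egg cohorts,
maturation of the adult cohorts' offspring, counting error in the
photographs, and any spatial or genetic structure among colonies. Passing
tests therefore demonstrate that the estimators recover the data-generating
process they assume, on data with the study's size and hierarchy — not that
the field estimates themselves are reproduced.

## Simulation studies (sizes and conditions)

* **Parameter recovery**: 200 experiments at the study design with
  mortality off (survival = 1), fitted with the default adaptive quadrature
  and no extra restarts. Median relative bias of k̂ and λ̂₀ is ~1%;
  σ̂_colony sits on the zero boundary in ~60% of replicates. Wald 95%
  coverage for β lands at the low end (~0.90): with 22 assays, maximum
  likelihood underestimates σ_assay (median 0.17 vs 0.2), a familiar
  small-sample variance-component bias that propagates into slightly narrow
  intervals. A REML-type correction is out of scope.
* **Randomization calibration**: 200 complete-null experiments (β = 0,
  equal survival 0.7), 199 colony-level permutations each, day-6 binomial
  GLMM statistic, permutation refits on the plain-quadrature path (order 9).
  Empirical size ≈ 0.03 at nominal 0.05 — mildly conservative, as expected
  from the discrete 165-assignment space and the add-one estimator.
* **Exhaustive vs sampled**: one default experiment; the 1000-draw sampled
  p agrees with the exact 165-assignment p to < 0.01.

The acceptance script reports single-experiment model fits at the default
(mortality-on) conditions; its pooled survival/fecundity summaries average
20 replicate experiments to suppress single-study binomial noise.

## Known limitations

* Censoring policy A conflates death with slow development by design (see
  above); with the default mortality levels the marginal Weibull shape is
  attenuated toward 1. Interpret shape estimates under mortality
  accordingly, or use `"drop-nonmatured"` when death counts are trustworthy.
* Wald intervals for the cultivar effect are slightly anti-conservative at
  the study's size; the randomization test is the recommended inference.
* The Poisson fecundity model identifies the female covariate only when
  some females die by day 2.
* No left truncation, no non-Weibull families beyond the exponential
  special case, and no multiple-testing correction across the three
  analyses.
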