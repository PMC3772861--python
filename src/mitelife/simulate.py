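"""Synthetic common-garden experiments with the structure the analyses assume.

The generator reproduces the hierarchical design (cultivar -> sample colony ->
assay population) and the photographic observation process:

* egg cohorts: individual development times are Weibull with survival
  ``S(t) = exp(-(lambda_ij t)^k)``, where ``log lambda_ij`` carries the fixed
  cultivar effect plus Normal colony and assay random effects; each individual
  independently survives the juvenile period with a cultivar-specific
  probability; survivors' maturation days are interval-censored onto the
  sampling grid (an event is first visible at the next sampling day);
* adult cohorts: eggs are laid as a Poisson process per surviving female,
  with log-normal colony/assay heterogeneity, and counted on the grid.

Per-assay random substreams are derived by stable hashing of the assay id, so
extending the design never perturbs the series already generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .cohorts import CohortCountSeries
from .design import ADULT, EGG, AssaySpec, ExperimentDesign, default_design
from .exceptions import ConfigurationError

_EGG_STAGE_DAYS = 2.0  # fixed egg duration used only to split egg/immature counts


def _substream(seed: int, *tags: str) -> np.random.Generator:
    """Deterministic child generator keyed by string tags (stable CRC32 hash)."""
    keys = [int(seed) & 0x7FFFFFFF]
    keys += [zlib.crc32(t.encode("utf8")) & 0x7FFFFFFF for t in tags]
    return np.random.default_rng(np.random.SeedSequence(keys))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic experiment.

    Development follows the Weibull time-to-event model with shape ``k``,
    baseline rate ``lambda0`` (1/day), cultivar effect ``beta`` on the log
    rate (indicator 1 = Zinfandel, so ``beta > 0`` means faster development on
    Zinfandel lines), and Normal colony/assay random effects with standard
    deviations ``sigma_colony`` and ``sigma_assay``. Juvenile survival and
    per-female fecundity carry their own cultivar levels and (logit/log scale)
    random-effect standard deviations.
    """

    design: ExperimentDesign = field(default_factory=default_design)
    # development (Weibull on the log-rate scale)
    shape: float = 2.5
    rate0: float = 0.2
    cultivar_effect: float = 0.3
    sigma_colony: float = 0.0
    sigma_assay: float = 0.2
    # juvenile survival to adulthood (probability scale; REs on logit scale)
    survival_zinfandel: float = 0.767
    survival_chardonnay: float = 0.633
    survival_sigma_colony: float = 0.0
    survival_sigma_assay: float = 0.3
    # fecundity (eggs per female per 2 days; REs on log scale)
    eggs_per_female_2d: float = 10.8
    fecundity_cultivar_effect: float = 0.0
    fecundity_sigma_colony: float = 0.0
    fecundity_sigma_assay: float = 0.15
    female_day2_survival: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate0 <= 0:
            raise ConfigurationError("Weibull shape and baseline rate must be positive")
        for name in ("sigma_colony", "sigma_assay", "survival_sigma_colony", "survival_sigma_assay",
                     "fecundity_sigma_colony", "fecundity_sigma_assay"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("survival_zinfandel", "survival_chardonnay", "female_day2_survival"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be a probability")
        if self.eggs_per_female_2d < 0:
            raise ConfigurationError("eggs_per_female_2d must be non-negative")

    def with_design(self, design: ExperimentDesign) -> "GeneratorConfig":
        return replace(self, design=design)


def sample_random_effects(config: GeneratorConfig) -> tuple[dict[str, float], dict[str, float]]:
    """Draw colony effects ``u_i ~ N(0, sigma_colony^2)`` and assay effects
    ``v_ij ~ N(0, sigma_assay^2)`` for the development model.

    ``log lambda_ij = log rate0 + beta * 1[Zinfandel] + u_i + v_ij``.
    Each effect comes from its own hash-keyed substream of the root seed.
    """
    u = {
        cid: config.sigma_colony * _substream(config.seed, "colony-dev", cid).standard_normal()
        for cid, _ in config.design.colonies
    }
    v = {
        a.assay_id: config.sigma_assay * _substream(config.seed, "assay-dev", a.assay_id).standard_normal()
        for a in config.design.assays()
    }
    return u, v


def simulate_development_times(
    n: int, shape: float, rate: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """I.i.d. Weibull development times with survival ``exp(-(rate*t)^shape)``."""
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    if shape <= 0 or rate <= 0:
        raise ConfigurationError("shape and rate must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return rng.weibull(shape, size=n) / rate


def censor_to_intervals(
    event_days: np.ndarray,
    design: ExperimentDesign,
    survival_p: float,
    rng: np.random.Generator | int | None = None,
    assay: AssaySpec | None = None,
) -> CohortCountSeries:
    """Render individual event days as a photographed egg-cohort count series.

    Each individual survives the juvenile period with probability
    ``survival_p``; non-survivors never appear as adults and their death day is
    drawn uniformly on ``(0, min(maturation, 4)]`` (it only shapes the
    intermediate stage counts, nothing the analyses use). A survivor maturing
    at ``t`` is first counted as an adult on the first sampling day ``>= t``.
    """
    event_days = np.asarray(event_days, dtype=float)
    if np.any(event_days < 0):
        raise ConfigurationError("event days must be non-negative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if assay is None:
        assay = AssaySpec("egg-cohort", "colony", design.colonies[0][1], EGG)
    n = event_days.size
    alive = rng.random(n) < survival_p
    death_day = np.full(n, np.inf)
    dead = ~alive
    # open at 0: a founding individual is always present in the day-0 photo
    death_day[dead] = np.maximum(rng.uniform(0.0, np.minimum(event_days[dead], 4.0)), 1e-9)
    days = np.asarray(design.sampling_days, dtype=float)
    eggs = np.zeros(days.size, dtype=int)
    imm = np.zeros(days.size, dtype=int)
    ad = np.zeros(days.size, dtype=int)
    for t, day in enumerate(days):
        present = death_day > day
        matured = alive & (event_days <= day)
        ad[t] = int(np.sum(matured))
        juvenile = present & ~matured
        still_egg = juvenile & (day < np.minimum(_EGG_STAGE_DAYS, event_days))
        eggs[t] = int(np.sum(still_egg))
        imm[t] = int(np.sum(juvenile & ~still_egg))
    return CohortCountSeries(
        assay_id=assay.assay_id,
        colony_id=assay.colony_id,
        cultivar=assay.cultivar,
        cohort_type=EGG,
        days=days.astype(int),
        eggs=eggs,
        immatures=imm,
        adults=ad,
        initial_size=n,
    )


def _simulate_adult_cohort(config: GeneratorConfig, assay: AssaySpec, log_fec_mult: float) -> CohortCountSeries:
    rng = _substream(config.seed, "assay-series", assay.assay_id)
    design = config.design
    n_f = design.adult_cohort_size
    days = np.asarray(design.sampling_days)
    # female survival: day-2 Bernoulli thinning, then constant
    surviving = int(rng.binomial(n_f, config.female_day2_survival))
    females = np.concatenate(([n_f], np.full(days.size - 1, surviving)))
    x = 1.0 if assay.cultivar == "Zinfandel" else 0.0
    mean_2d = config.eggs_per_female_2d * np.exp(config.fecundity_cultivar_effect * x + log_fec_mult)
    # eggs laid per interval by the females alive over that interval
    laid = np.zeros(days.size, dtype=int)
    for t in range(1, days.size):
        frac = (days[t] - days[t - 1]) / 2.0
        laid[t] = rng.poisson(mean_2d * frac * females[t])
    cum = np.cumsum(laid)
    # a laid egg hatches after the fixed egg stage; offspring maturation is not
    # rendered (adult-cohort series only feed the day-2 fecundity dataset)
    hatched = np.concatenate((np.zeros(1, dtype=int), cum[:-1]))  # eggs older than one interval
    eggs = cum - hatched
    return CohortCountSeries(
        assay_id=assay.assay_id,
        colony_id=assay.colony_id,
        cultivar=assay.cultivar,
        cohort_type=ADULT,
        days=days,
        eggs=eggs,
        immatures=hatched,
        adults=females,
        initial_size=n_f,
    )


def simulate_experiment(config: GeneratorConfig) -> list[CohortCountSeries]:
    """Simulate one complete experiment; deterministic given ``config.seed``."""
    design = config.design
    u_dev, v_dev = sample_random_effects(config)
    from scipy.special import expit, logit  # local import keeps module import light

    out: list[CohortCountSeries] = []
    for assay in design.assays():
        x = 1.0 if assay.cultivar == "Zinfandel" else 0.0
        if assay.cohort_type == EGG:
            rng = _substream(config.seed, "assay-series", assay.assay_id)
            rate = config.rate0 * np.exp(
                config.cultivar_effect * x + u_dev[assay.colony_id] + v_dev[assay.assay_id]
            )
            times = simulate_development_times(design.egg_cohort_size, config.shape, rate, rng)
            p0 = config.survival_zinfandel if x else config.survival_chardonnay
            u_s = config.survival_sigma_colony * _substream(config.seed, "colony-surv", assay.colony_id).standard_normal()
            v_s = config.survival_sigma_assay * _substream(config.seed, "assay-surv", assay.assay_id).standard_normal()
            p = float(expit(logit(np.clip(p0, 1e-12, 1 - 1e-12)) + u_s + v_s)) if (u_s or v_s) else p0
            out.append(censor_to_intervals(times, design, p, rng, assay))
        else:
            u_f = config.fecundity_sigma_colony * _substream(config.seed, "colony-fec", assay.colony_id).standard_normal()
            v_f = config.fecundity_sigma_assay * _substream(config.seed, "assay-fec", assay.assay_id).standard_normal()
            out.append(_simulate_adult_cohort(config, assay, u_f + v_f))
    return out
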