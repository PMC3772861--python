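import logging

import numpy as np
import pytest

import mitelife as ml
from mitelife.cohorts import IntervalEventData

# GLMM separation / zero-trial warnings are expected in permutation loops
logging.getLogger("mitelife").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_experiment():
    """One simulated experiment at the study design and generator defaults."""
    cfg = ml.GeneratorConfig(seed=17)
    return cfg, ml.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def derived(default_experiment):
    _, series = default_experiment
    return ml.derive_analysis_datasets(series)


@pytest.fixture(scope="session")
def toy_intervals():
    """Two colonies x two assays with a 4-interval partition of (0, 8]."""
    specs = [
        ("c1", "a11", "Zinfandel", [2, 3, 3, 1], 1),
        ("c1", "a12", "Zinfandel", [1, 4, 2, 2], 1),
        ("c2", "a21", "Chardonnay", [0, 2, 4, 2], 2),
        ("c2", "a22", "Chardonnay", [1, 1, 5, 2], 1),
    ]
    return [
        IntervalEventData(aid, col, cv, [0, 2, 4, 6], [2, 4, 6, 8], m, rc, 10)
        for col, aid, cv, m, rc in specs
    ]


@pytest.fixture(scope="session")
def tte_fits(derived):
    """Full and null Weibull frailty fits on the default simulated intervals."""
    full = ml.fit_mle(derived["intervals"], model="cultivar", n_restarts=0)
    null = ml.fit_mle(derived["intervals"], model="null", n_restarts=0)
    return full, null


def make_series(adults, cohort_type="egg", initial=10, assay_id="a1",
                colony_id="c1", cultivar="Zinfandel"):
    """Egg-cohort series with the given adult counts on days 0..12; the
    egg/immature split is backfilled to keep stage counts consistent."""
    adults = np.asarray(adults)
    days = np.arange(0, 2 * len(adults), 2)
    eggs = np.zeros_like(adults)
    eggs[0] = initial if cohort_type == "egg" else 0
    imm = np.maximum(initial - adults - eggs, 0) if cohort_type == "egg" else np.zeros_like(adults)
    if cohort_type == "egg":
        imm[0] = 0
    return ml.CohortCountSeries(
        assay_id=assay_id, colony_id=colony_id, cultivar=cultivar,
        cohort_type=cohort_type, days=days, eggs=eggs, immatures=imm,
        adults=adults, initial_size=initial,
    )
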