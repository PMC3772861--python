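"""Likelihood-ratio inference on the cultivar effect.

Two null distributions for the statistic ``D = 2 (loglik_full - loglik_null)``:

* the large-sample chi-squared approximation, and
* a randomization distribution built by permuting cultivar labels at the
  sample-colony level (labels travel with all of a colony's assay
  populations, preserving the hierarchy and the observed 8/3 split) and
  refitting both models per permutation. The small number of colonies makes
  the chi-squared approximation questionable, which is what motivates the
  randomization test; an exhaustive mode enumerates all distinct label
  assignments (C(11,3) = 165 for the default design) for an exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .exceptions import DataError
from .cohorts import IntervalEventData

logger = logging.getLogger(__name__)

_D_TOL = 1e-6  # optimizer noise allowance on D >= 0


@dataclass
class LrtResult:
    """Likelihood-ratio statistic with chi-squared and randomization p-values."""

    D: float
    df: int
    p_chisq: float
    p_perm: float | None = None
    n_perm: int = 0
    null_distribution: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> dict:
        out = {"D": self.D, "df": self.df, "p_chisq": self.p_chisq}
        if self.p_perm is not None:
            out.update({"p_perm": self.p_perm, "n_perm": self.n_perm})
        return out


def _loglik_of(fit) -> float:
    if hasattr(fit, "loglik_"):
        return float(fit.loglik_)
    if hasattr(fit, "loglik"):
        return float(fit.loglik)
    return float(fit)


def lrt(full, null, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio statistic and upper-tail chi-squared p-value.

    ``full``/``null`` may be fitted models or log-likelihood values. A
    negative statistic beyond optimizer tolerance means the nested null fit
    beat the full fit and signals a failed maximization.
    """
    ll_full, ll_null = _loglik_of(full), _loglik_of(null)
    D = 2.0 * (ll_full - ll_null)
    if D < -_D_TOL * max(1.0, abs(ll_full)):
        raise DataError(
            f"full model log-likelihood {ll_full:.6f} below null {ll_null:.6f}; refit with restarts"
        )
    D = max(D, 0.0)
    return D, float(chi2.sf(D, df))


def enumerate_label_assignments(colonies, n_minority: int,
                                labels: tuple[str, str] = ("Zinfandel", "Chardonnay"),
                                limit: int = 1_000_000) -> list[dict]:
    """All distinct assignments of the two cultivar labels to colonies with
    exactly ``n_minority`` colonies carrying ``labels[1]``.

    Returns ``C(n, m)`` dicts mapping colony id to label, each distinct and
    including (when the observed split matches) the observed assignment.
    """
    colonies = list(colonies)
    n = len(colonies)
    if n_minority > n:
        raise ValueError("n_minority cannot exceed the number of colonies")
    total = comb(n, n_minority)
    if total > limit:
        raise ValueError(f"{total} assignments exceed the enumeration guard of {limit}")
    majority, minority = labels
    out = []
    for chosen in combinations(range(n), n_minority):
        chosen = set(chosen)
        out.append({c: (minority if i in chosen else majority) for i, c in enumerate(colonies)})
    return out


def _unit_labels(data, unit: str) -> dict[str, str]:
    """Observed label of each permutation unit (colony or assay)."""
    if isinstance(data, pd.DataFrame):
        pairs = data[[unit, "cultivar"]].drop_duplicates()
        mapping = dict(zip(pairs[unit], pairs["cultivar"]))
        if len(mapping) != pairs[unit].nunique():  # pragma: no cover - defensive
            raise DataError(f"{unit} maps to more than one cultivar")
        return mapping
    # list of record-like objects (IntervalEventData, BinaryOutcomeData, ...)
    mapping: dict[str, str] = {}
    for rec in data:
        key = getattr(rec, unit)
        cv = rec.cultivar
        if mapping.setdefault(key, cv) != cv:
            raise DataError(f"{unit} {key} maps to more than one cultivar")
    return mapping


def _relabel(data, unit: str, mapping: dict[str, str]):
    if isinstance(data, pd.DataFrame):
        out = data.copy()
        out["cultivar"] = out[unit].map(mapping)
        return out
    out = []
    for rec in data:
        new = type(rec)(**{**rec.__dict__, "cultivar": mapping[getattr(rec, unit)]})
        out.append(new)
    return out


def randomization_test(
    data,
    fitter,
    n_perm: int = 1000,
    seed: int | None = 0,
    df: int = 1,
    unit: str = "colony_id",
    exhaustive: bool = False,
    cache: bool = True,
    max_failure_frac: float = 0.05,
) -> LrtResult:
    """Randomization likelihood-ratio test of the cultivar effect.

    ``fitter(data) -> D`` must refit the full and null models on the
    (relabelled) dataset and return the likelihood-ratio statistic. Labels
    are permuted over sample colonies by default (``unit="assay_id"`` permutes
    at the assay level for sensitivity analysis), preserving the observed
    label counts. Each permutation index gets its own seeded substream, so
    results are reproducible and independent of evaluation order. Identical
    label assignments are fitted once when ``cache`` is set (the assignment
    space is small: C(11, 3) = 165 for the default design).

    The sampled p-value uses the add-one estimator
    ``(1 + #{D_perm >= D_obs}) / (n_ok + 1)``; in exhaustive mode every
    distinct assignment is evaluated once and the p-value is the exact
    fraction ``#{D >= D_obs} / N`` (the observed assignment is included).
    """
    observed = _unit_labels(data, unit)
    units = sorted(observed)
    obs_labels = [observed[u] for u in units]
    level_counts = pd.Series(obs_labels).value_counts()
    if len(level_counts) != 2:
        raise DataError("randomization test requires exactly two cultivar levels")
    D_obs = float(fitter(data))
    memo: dict[tuple, float] = {tuple(obs_labels): D_obs}

    null_D: list[float] = []
    failures = 0

    def eval_assignment(labels: tuple) -> float | None:
        nonlocal failures
        if cache and labels in memo:
            return memo[labels]
        try:
            d = float(fitter(_relabel(data, unit, dict(zip(units, labels)))))
        except Exception as exc:  # refit failure: drop the replicate
            failures += 1
            logger.warning("permutation refit failed (%s)", exc)
            return None
        if cache:
            memo[labels] = d
        return d

    if exhaustive:
        minority = level_counts.index[-1]
        majority = level_counts.index[0]
        assignments = enumerate_label_assignments(
            units, int(level_counts.iloc[-1]), labels=(majority, minority))
        for mapping in assignments:
            d = eval_assignment(tuple(mapping[u] for u in units))
            if d is not None:
                null_D.append(d)
        if failures:
            raise DataError(f"{failures} refit failure(s) in exhaustive mode")
        null_D = np.asarray(null_D)
        p_perm = float(np.mean(null_D >= D_obs - 1e-9))
        n_ok = null_D.size
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        base = 0 if seed is None else int(seed)
        pool = np.array(obs_labels)
        for i in range(n_perm):
            rng = np.random.default_rng(np.random.SeedSequence([base & 0x7FFFFFFF, i]))
            d = eval_assignment(tuple(pool[rng.permutation(pool.size)]))
            if d is not None:
                null_D.append(d)
        if failures > max_failure_frac * n_perm:
            raise DataError(f"{failures}/{n_perm} permutation refits failed")
        null_D = np.asarray(null_D)
        n_ok = null_D.size
        p_perm = float((1 + np.sum(null_D >= D_obs - 1e-9)) / (n_ok + 1))

    return LrtResult(
        D=D_obs,
        df=df,
        p_chisq=float(chi2.sf(max(D_obs, 0.0), df)),
        p_perm=p_perm,
        n_perm=int(n_ok),
        null_distribution=null_D,
    )
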