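"""Cohort count series and the three analysis datasets derived from them.

Photographic sampling yields, for every assay population and sampling day,
counts of eggs, immatures and adults. Three datasets feed the analyses:

* interval-censored maturation counts from the adult-count increments of
  egg cohorts (time-to-event model and day-6 GLMM),
* day-4 juvenile survival out of the initial eggs (binomial GLMM),
* day-2 egg counts of adult cohorts (Poisson GLMM).

Maturations are inferred with a running-max rule: a rise of the adult count
above its previous maximum means that many immatures matured during the
interval; dips (adult deaths) are never allowed to cause double counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ADULT, EGG, ExperimentDesign
from .exceptions import ConfigurationError, DataError, SchemaError

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["assay_id", "colony_id", "cultivar", "cohort_type", "day", "eggs", "immatures", "adults"]


@dataclass
class CohortCountSeries:
    """Stage counts of one assay population over the sampling schedule."""

    assay_id: str
    colony_id: str
    cultivar: str
    cohort_type: str
    days: np.ndarray
    eggs: np.ndarray
    immatures: np.ndarray
    adults: np.ndarray
    initial_size: int

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.eggs = np.asarray(self.eggs, dtype=int)
        self.immatures = np.asarray(self.immatures, dtype=int)
        self.adults = np.asarray(self.adults, dtype=int)
        n = self.days.size
        if any(a.size != n for a in (self.eggs, self.immatures, self.adults)):
            raise SchemaError(f"{self.assay_id}: stage-count arrays must match the day grid")
        d = np.diff(self.days)
        if n < 2 or np.any(d <= 0) or np.any(d != d[0]):
            raise SchemaError(f"{self.assay_id}: sampling days must be strictly increasing and equally spaced")
        if min(self.eggs.min(), self.immatures.min(), self.adults.min()) < 0:
            raise DataError(f"{self.assay_id}: negative stage count")
        if self.cohort_type == EGG:
            if self.adults[0] > 0:
                raise DataError(f"{self.assay_id}: egg cohort cannot start with adults present")
            if self.eggs[0] != self.initial_size:
                raise DataError(
                    f"{self.assay_id}: egg cohort must start with {self.initial_size} eggs, got {self.eggs[0]}"
                )
        elif self.cohort_type == ADULT:
            if self.adults[0] != self.initial_size:
                raise DataError(
                    f"{self.assay_id}: adult cohort must start with {self.initial_size} adults, got {self.adults[0]}"
                )
        else:
            raise SchemaError(f"unknown cohort_type {self.cohort_type!r}")

    @property
    def sample_interval(self) -> int:
        return int(self.days[1] - self.days[0])


@dataclass
class IntervalEventData:
    """Per-assay maturation counts on the interval partition of the study.

    ``lower``/``upper`` bound each sampling interval ``(lower, upper]`` and
    together partition ``(0, study_length]``. ``matured[i]`` individuals were
    inferred to mature in interval ``i``; ``right_censored`` individuals were
    never observed as adults and are carried at the study end.
    """

    assay_id: str
    colony_id: str
    cultivar: str
    lower: np.ndarray
    upper: np.ndarray
    matured: np.ndarray
    right_censored: int
    initial_size: int

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.matured = np.asarray(self.matured, dtype=int)
        if not (self.lower.size == self.upper.size == self.matured.size):
            raise SchemaError(f"{self.assay_id}: ragged interval arrays")
        if np.any(self.upper <= self.lower):
            raise DataError(f"{self.assay_id}: intervals need lower < upper")
        if np.any(self.lower[1:] != self.upper[:-1]) or (self.lower.size and self.lower[0] != 0):
            raise DataError(f"{self.assay_id}: intervals must partition (0, study_length]")
        if self.matured.min(initial=0) < 0 or self.right_censored < 0:
            raise DataError(f"{self.assay_id}: negative event count")
        if self.matured.sum() + self.right_censored > self.initial_size:
            raise DataError(f"{self.assay_id}: more events than individuals")

    @property
    def study_length(self) -> float:
        return float(self.upper[-1])

    @property
    def total_matured(self) -> int:
        return int(self.matured.sum())


@dataclass
class BinaryOutcomeData:
    """Successes out of trials for one assay population."""

    assay_id: str
    colony_id: str
    cultivar: str
    successes: int
    trials: int

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.trials:
            raise DataError(f"{self.assay_id}: need 0 <= successes <= trials")


@dataclass
class FecundityData:
    """Day-2 egg count of an adult cohort plus the surviving-female covariate."""

    assay_id: str
    colony_id: str
    cultivar: str
    eggs_day2: int
    surviving_females_day2: int

    def __post_init__(self) -> None:
        if self.eggs_day2 < 0:
            raise DataError(f"{self.assay_id}: negative egg count")
        if self.surviving_females_day2 < 0:
            raise DataError(f"{self.assay_id}: negative female count")


# ---------------------------------------------------------------------------
# derivations
# ---------------------------------------------------------------------------

def derive_maturation_intervals(
    series: CohortCountSeries, censoring: str = "censor-nonmatured"
) -> IntervalEventData:
    """Infer interval-censored maturation counts from an egg cohort.

    The count maturing in ``(d[t-1], d[t]]`` is the positive increment of the
    adult count above its running maximum, so adult deaths (dips in the adult
    count) never produce double counting.

    With the default censoring policy every individual never seen as an adult
    by the study end -- including any that died as juveniles -- contributes a
    right-censored observation at ``study_length``. The alternative policy
    ``"drop-nonmatured"`` removes them from the risk set entirely (no
    right-censored mass); individual death times are unobservable, so there is
    no policy that censors at death.
    """
    if series.cohort_type != EGG:
        raise DataError(f"{series.assay_id}: maturation intervals require an egg cohort")
    if censoring not in ("censor-nonmatured", "drop-nonmatured"):
        raise ConfigurationError(f"unknown censoring policy {censoring!r}")
    adults = series.adults
    running_max = np.maximum.accumulate(adults)
    prev_max = np.concatenate(([0], running_max[:-1]))
    inc = np.maximum(0, adults - prev_max)[1:]  # one entry per interval
    total = int(np.maximum.accumulate(adults)[-1])
    if censoring == "censor-nonmatured":
        right_censored = series.initial_size - total
    else:
        right_censored = 0
    return IntervalEventData(
        assay_id=series.assay_id,
        colony_id=series.colony_id,
        cultivar=series.cultivar,
        lower=series.days[:-1].astype(float),
        upper=series.days[1:].astype(float),
        matured=inc,
        right_censored=right_censored,
        initial_size=series.initial_size,
    )


def dichotomize_day6(
    interval_data: IntervalEventData, cutoff: float = 6.0, denominator: str = "matured"
) -> BinaryOutcomeData:
    """Collapse maturation intervals into matured-by-day-``cutoff`` or later.

    Successes are maturations in intervals with ``upper <= cutoff`` (an
    individual first seen adult exactly on the cutoff day counts as early).
    With the default denominator, trials are the individuals that matured at
    any time during the study, partitioning maturers into early and late;
    ``denominator="initial"`` uses the founding cohort size instead.
    """
    if cutoff not in interval_data.upper:
        raise ConfigurationError(
            f"day {cutoff} is not an interval boundary for {interval_data.assay_id}"
        )
    early = int(interval_data.matured[interval_data.upper <= cutoff].sum())
    if denominator == "matured":
        trials = interval_data.total_matured
    elif denominator == "initial":
        trials = interval_data.initial_size
    else:
        raise ConfigurationError(f"unknown denominator {denominator!r}")
    if trials == 0:
        logger.warning("%s: no individual matured; zero-trial record flagged", interval_data.assay_id)
    return BinaryOutcomeData(
        assay_id=interval_data.assay_id,
        colony_id=interval_data.colony_id,
        cultivar=interval_data.cultivar,
        successes=early,
        trials=trials,
    )


def derive_survival_day4(series: CohortCountSeries, day: int = 4) -> BinaryOutcomeData:
    """Juveniles alive on day ``day`` out of the initial eggs of an egg cohort.

    Day 4 is early enough that no individual should have matured, so every
    survivor is still an egg or immature; any adults present are nonetheless
    counted as alive, and the total is capped at the founding size.
    """
    if series.cohort_type != EGG:
        raise DataError(f"{series.assay_id}: day-{day} survival requires an egg cohort")
    if day not in series.days:
        raise ConfigurationError(f"day {day} is not a sampling day for {series.assay_id}")
    t = int(np.flatnonzero(series.days == day)[0])
    alive = int(series.eggs[t] + series.immatures[t] + series.adults[t])
    return BinaryOutcomeData(
        assay_id=series.assay_id,
        colony_id=series.colony_id,
        cultivar=series.cultivar,
        successes=min(alive, series.initial_size),
        trials=series.initial_size,
    )


def derive_fecundity_day2(series: CohortCountSeries, day: int = 2) -> FecundityData:
    """Day-2 egg count of an adult cohort and the surviving females covariate."""
    if series.cohort_type != ADULT:
        raise DataError(f"{series.assay_id}: fecundity requires an adult cohort")
    if day not in series.days:
        raise ConfigurationError(f"day {day} is not a sampling day for {series.assay_id}")
    t = int(np.flatnonzero(series.days == day)[0])
    return FecundityData(
        assay_id=series.assay_id,
        colony_id=series.colony_id,
        cultivar=series.cultivar,
        eggs_day2=int(series.eggs[t]),
        surviving_females_day2=int(series.adults[t]),
    )


def derive_analysis_datasets(
    series_list: list[CohortCountSeries],
    censoring: str = "censor-nonmatured",
    day6: float = 6.0,
    day4: int = 4,
    day2: int = 2,
    day6_denominator: str = "matured",
) -> dict:
    """Derive all three analysis datasets from a full experiment's series."""
    intervals = [derive_maturation_intervals(s, censoring) for s in series_list if s.cohort_type == EGG]
    return {
        "intervals": intervals,
        "day6": [dichotomize_day6(iv, day6, day6_denominator) for iv in intervals],
        "survival": [derive_survival_day4(s, day4) for s in series_list if s.cohort_type == EGG],
        "fecundity": [derive_fecundity_day2(s, day2) for s in series_list if s.cohort_type == ADULT],
    }


# ---------------------------------------------------------------------------
# tabular interchange
# ---------------------------------------------------------------------------

def _require_columns(frame: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def series_to_frame(series_list: list[CohortCountSeries]) -> pd.DataFrame:
    """Long-format counts table, one row per assay population and sampling day."""
    rows = []
    for s in series_list:
        for i, day in enumerate(s.days):
            rows.append(
                (s.assay_id, s.colony_id, s.cultivar, s.cohort_type, int(day),
                 int(s.eggs[i]), int(s.immatures[i]), int(s.adults[i]))
            )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def frame_to_series(frame: pd.DataFrame, design: ExperimentDesign | None = None) -> list[CohortCountSeries]:
    """Rebuild per-assay count series from a long-format counts table."""
    _require_columns(frame, COUNT_COLUMNS, "counts table")
    out = []
    for assay_id, g in frame.groupby("assay_id", sort=True):
        g = g.sort_values("day")
        ctype = g["cohort_type"].iloc[0]
        if design is not None:
            initial = design.egg_cohort_size if ctype == EGG else design.adult_cohort_size
        else:
            initial = int(g["eggs"].iloc[0] if ctype == EGG else g["adults"].iloc[0])
        out.append(
            CohortCountSeries(
                assay_id=str(assay_id),
                colony_id=str(g["colony_id"].iloc[0]),
                cultivar=str(g["cultivar"].iloc[0]),
                cohort_type=str(ctype),
                days=g["day"].to_numpy(),
                eggs=g["eggs"].to_numpy(),
                immatures=g["immatures"].to_numpy(),
                adults=g["adults"].to_numpy(),
                initial_size=initial,
            )
        )
    return out


def intervals_to_frame(intervals: list[IntervalEventData]) -> pd.DataFrame:
    rows = []
    for iv in intervals:
        for lo, up, m in zip(iv.lower, iv.upper, iv.matured):
            rows.append((iv.assay_id, iv.colony_id, iv.cultivar, float(lo), float(up), int(m),
                         int(iv.right_censored), int(iv.initial_size)))
    return pd.DataFrame(
        rows,
        columns=["assay_id", "colony_id", "cultivar", "lower", "upper", "matured",
                 "right_censored", "initial_size"],
    )


def frame_to_intervals(frame: pd.DataFrame) -> list[IntervalEventData]:
    _require_columns(
        frame,
        ["assay_id", "colony_id", "cultivar", "lower", "upper", "matured", "right_censored", "initial_size"],
        "intervals table",
    )
    out = []
    for assay_id, g in frame.groupby("assay_id", sort=True):
        g = g.sort_values("lower")
        out.append(
            IntervalEventData(
                assay_id=str(assay_id),
                colony_id=str(g["colony_id"].iloc[0]),
                cultivar=str(g["cultivar"].iloc[0]),
                lower=g["lower"].to_numpy(),
                upper=g["upper"].to_numpy(),
                matured=g["matured"].to_numpy(),
                right_censored=int(g["right_censored"].iloc[0]),
                initial_size=int(g["initial_size"].iloc[0]),
            )
        )
    return out


def binary_to_frame(data: list[BinaryOutcomeData]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.assay_id, d.colony_id, d.cultivar, d.successes, d.trials) for d in data],
        columns=["assay_id", "colony_id", "cultivar", "successes", "trials"],
    )


def frame_to_binary(frame: pd.DataFrame) -> list[BinaryOutcomeData]:
    _require_columns(frame, ["assay_id", "colony_id", "cultivar", "successes", "trials"], "binary table")
    return [
        BinaryOutcomeData(str(r.assay_id), str(r.colony_id), str(r.cultivar), int(r.successes), int(r.trials))
        for r in frame.itertuples()
    ]


def fecundity_to_frame(data: list[FecundityData]) -> pd.DataFrame:
    return pd.DataFrame(
        [(d.assay_id, d.colony_id, d.cultivar, d.eggs_day2, d.surviving_females_day2) for d in data],
        columns=["assay_id", "colony_id", "cultivar", "eggs_day2", "surviving_females_day2"],
    )


def frame_to_fecundity(frame: pd.DataFrame) -> list[FecundityData]:
    _require_columns(
        frame, ["assay_id", "colony_id", "cultivar", "eggs_day2", "surviving_females_day2"], "fecundity table"
    )
    return [
        FecundityData(str(r.assay_id), str(r.colony_id), str(r.cultivar), int(r.eggs_day2),
                      int(r.surviving_females_day2))
        for r in frame.itertuples()
    ]
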