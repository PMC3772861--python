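"""Experimental design of the common-garden cohort assay.

The hierarchy is cultivar -> sample colony -> assay population -> individual.
Each sample colony (founded from mites collected in one vineyard) contributes
a fixed number of egg-initiated and adult-initiated assay populations, each
reared on its own trimmed bean plant and photographed on a regular schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .exceptions import ConfigurationError, DataError

#: The two source-cultivar levels. The fixed-effect indicator is 1 for
#: Zinfandel, so a positive cultivar effect on the log maturation rate means
#: faster development in Zinfandel-sourced lines.
CULTIVARS = ("Zinfandel", "Chardonnay")

EGG = "egg"
ADULT = "adult"


@dataclass(frozen=True)
class AssaySpec:
    """Identity and provenance of one assay population."""

    assay_id: str
    colony_id: str
    cultivar: str
    cohort_type: str  # EGG or ADULT


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of colonies, cohorts and the photographic sampling schedule.

    Parameters
    ----------
    colonies
        Sequence of ``(colony_id, cultivar)`` pairs; at most two cultivar
        levels may appear.
    egg_cohorts, adult_cohorts
        Number of egg-initiated / adult-initiated assay populations founded
        from each colony.
    egg_cohort_size
        Eggs transferred to found an egg cohort.
    adult_cohort_size
        Mated females founding an adult cohort.
    sample_interval
        Days between photographic samples.
    study_length
        Total duration in days; must be a multiple of ``sample_interval``.
    """

    colonies: tuple[tuple[str, str], ...]
    egg_cohorts: int = 2
    adult_cohorts: int = 2
    egg_cohort_size: int = 10
    adult_cohort_size: int = 5
    sample_interval: int = 2
    study_length: int = 12

    def __post_init__(self) -> None:
        object.__setattr__(self, "colonies", tuple((str(c), str(v)) for c, v in self.colonies))
        if not self.colonies:
            raise DataError("design needs at least one colony")
        ids = [c for c, _ in self.colonies]
        if len(set(ids)) != len(ids):
            raise DataError("colony ids must be unique")
        levels = {v for _, v in self.colonies}
        if len(levels) > 2:
            raise DataError(f"cultivar labels must have at most two levels, got {sorted(levels)}")
        for name in ("egg_cohorts", "adult_cohorts"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("egg_cohort_size", "adult_cohort_size", "sample_interval", "study_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.study_length % self.sample_interval != 0:
            raise ConfigurationError("study_length must be a multiple of sample_interval")

    @property
    def sampling_days(self) -> tuple[int, ...]:
        return tuple(range(0, self.study_length + 1, self.sample_interval))

    @property
    def n_occasions(self) -> int:
        return self.study_length // self.sample_interval + 1

    @property
    def cultivar_levels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, v in self.colonies:
            if v not in seen:
                seen.append(v)
        return tuple(seen)

    def cultivar_of(self, colony_id: str) -> str:
        for cid, v in self.colonies:
            if cid == colony_id:
                return v
        raise KeyError(colony_id)

    def assays(self) -> Iterator[AssaySpec]:
        """Yield every assay population in a stable, deterministic order."""
        for cid, cultivar in self.colonies:
            for i in range(self.egg_cohorts):
                yield AssaySpec(f"{cid}-E{i + 1}", cid, cultivar, EGG)
            for i in range(self.adult_cohorts):
                yield AssaySpec(f"{cid}-A{i + 1}", cid, cultivar, ADULT)

    @property
    def n_assays(self) -> int:
        return len(self.colonies) * (self.egg_cohorts + self.adult_cohorts)


def default_design() -> ExperimentDesign:
    """The study design: 8 Zinfandel and 3 Chardonnay sample colonies, two egg
    cohorts of 10 and two adult cohorts of 5 each, photographed every 2 days
    for 12 days."""
    colonies = tuple((f"Z{i:02d}", "Zinfandel") for i in range(1, 9)) + tuple(
        (f"C{i:02d}", "Chardonnay") for i in range(1, 4)
    )
    return ExperimentDesign(colonies=colonies)
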