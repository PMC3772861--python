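"""Derivation of the three analysis datasets from photographic count series."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mitelife as ml
from mitelife.cohorts import (derive_fecundity_day2, derive_maturation_intervals,
                              derive_survival_day4, dichotomize_day6,
                              frame_to_intervals, frame_to_series,
                              intervals_to_frame, series_to_frame)
from mitelife.exceptions import ConfigurationError, DataError, SchemaError

from conftest import make_series


@pytest.mark.parametrize(
    "adults, expected_matured, expected_censored",
    [
        ([0, 0, 2, 5, 9, 10, 10], [0, 2, 3, 4, 1, 0], 0),
        ([0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0], 10),
        # dip at day 4 is an adult death; the running max prevents double counting
        ([0, 1, 0, 2, 2, 2, 2], [1, 0, 1, 0, 0, 0], 8),
    ],
)
def test_maturation_intervals_running_max(adults, expected_matured, expected_censored):
    iv = derive_maturation_intervals(make_series(adults))
    assert iv.matured.tolist() == expected_matured
    assert iv.right_censored == expected_censored
    assert iv.lower.tolist() == [0, 2, 4, 6, 8, 10]
    assert iv.upper.tolist() == [2, 4, 6, 8, 10, 12]


def test_maturation_requires_egg_cohort_and_clean_series():
    with pytest.raises(DataError):
        derive_maturation_intervals(make_series([5, 5, 5], cohort_type="adult", initial=5))
    with pytest.raises(DataError, match="egg cohort"):
        make_series([1, 2, 3])  # adults present at day 0 in an egg cohort
    with pytest.raises(SchemaError):
        ml.CohortCountSeries("a", "c", "Zinfandel", "egg", days=[0, 4, 6],
                             eggs=[10, 0, 0], immatures=[0, 10, 10],
                             adults=[0, 0, 0], initial_size=10)


def test_drop_nonmatured_censoring_policy():
    iv = derive_maturation_intervals(make_series([0, 0, 2, 5, 7, 7, 7]),
                                     censoring="drop-nonmatured")
    assert iv.right_censored == 0
    assert iv.total_matured == 7


@pytest.mark.parametrize(
    "matured, successes, trials",
    [
        ([0, 2, 3, 4, 1, 0], 5, 10),   # early = intervals with upper <= 6
        ([3, 0, 0, 0, 0, 0], 3, 3),    # everyone matured in (0, 2]
        ([0, 0, 0, 0, 0, 0], 0, 0),    # nobody matured: zero-trial record
    ],
)
def test_dichotomize_day6(matured, successes, trials):
    iv = ml.IntervalEventData("a", "c", "Zinfandel", [0, 2, 4, 6, 8, 10],
                              [2, 4, 6, 8, 10, 12], matured,
                              10 - int(np.sum(matured)), 10)
    out = dichotomize_day6(iv)
    assert (out.successes, out.trials) == (successes, trials)


def test_dichotomize_denominator_and_boundary():
    iv = ml.IntervalEventData("a", "c", "Zinfandel", [0, 2, 4, 6, 8, 10],
                              [2, 4, 6, 8, 10, 12], [0, 2, 3, 4, 1, 0], 0, 10)
    assert dichotomize_day6(iv, denominator="initial").trials == 10
    with pytest.raises(ConfigurationError):
        dichotomize_day6(iv, cutoff=5)


def test_survival_day4_counts_and_cap():
    s = make_series([0, 0, 0, 2, 5, 7, 7])
    s.eggs[:] = 0
    s.immatures[:] = 7  # 7 juveniles present on every day
    out = derive_survival_day4(s)
    assert (out.successes, out.trials) == (7, 10)
    s.immatures[:] = 12  # miscount above the founding size is capped
    assert derive_survival_day4(s).successes == 10
    with pytest.raises(ConfigurationError):
        derive_survival_day4(s, day=5)


def test_fecundity_day2():
    days = np.arange(0, 14, 2)
    s = ml.CohortCountSeries("a", "c", "Chardonnay", "adult", days,
                             eggs=[0, 54, 50, 50, 50, 50, 50],
                             immatures=[0, 0, 54, 104, 154, 204, 254],
                             adults=[5, 5, 5, 5, 5, 5, 5], initial_size=5)
    out = derive_fecundity_day2(s)
    assert (out.eggs_day2, out.surviving_females_day2) == (54, 5)
    s.adults[1:] = 0  # all females dead: record retained with covariate 0
    assert derive_fecundity_day2(s).surviving_females_day2 == 0


@given(st.lists(st.integers(min_value=0, max_value=10), min_size=6, max_size=6))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_total_matured_equals_final_running_max(adult_tail):
    adults = [0] + adult_tail
    iv = derive_maturation_intervals(make_series(adults))
    assert iv.total_matured == int(np.maximum.accumulate(adults)[-1])
    assert iv.total_matured + iv.right_censored == 10
    assert np.all(iv.matured >= 0)


@given(st.lists(st.floats(min_value=0.1, max_value=14.0), min_size=1, max_size=10),
       st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_round_trip_simulated_events_no_deaths(event_days, seed):
    """With no mortality, binning events through the observation process and
    re-deriving intervals recovers the per-interval counts exactly."""
    design = ml.default_design()
    series = ml.censor_to_intervals(np.array(event_days), design, survival_p=1.0,
                                    rng=np.random.default_rng(seed))
    iv = derive_maturation_intervals(series)
    days = np.asarray(design.sampling_days, float)
    # events binned right-closed: event at t lands in the interval whose upper
    # bound is the first sampling day >= t
    expected = np.array([
        sum(1 for t in event_days if lo < np.ceil(t / 2) * 2 <= up)
        for lo, up in zip(days[:-1], days[1:])
    ])
    assert iv.matured.tolist() == expected.tolist()
    assert iv.right_censored == sum(1 for t in event_days if t > design.study_length)


def test_counts_and_intervals_csv_round_trip(tmp_path, default_experiment):
    _, series = default_experiment
    frame = series_to_frame(series)
    path = tmp_path / "counts.csv"
    frame.to_csv(path, index=False)
    back = frame_to_series(pd.read_csv(path))
    assert len(back) == len(series)
    orig = {s.assay_id: s for s in series}
    for s in back:
        np.testing.assert_array_equal(s.adults, orig[s.assay_id].adults)
        np.testing.assert_array_equal(s.eggs, orig[s.assay_id].eggs)
    ivs = [derive_maturation_intervals(s) for s in series if s.cohort_type == "egg"]
    back_iv = {d.assay_id: d for d in frame_to_intervals(intervals_to_frame(ivs))}
    assert all(back_iv[d.assay_id].matured.tolist() == d.matured.tolist() for d in ivs)


def test_schema_error_names_missing_column():
    with pytest.raises(SchemaError, match="cultivar"):
        frame_to_series(pd.DataFrame({"assay_id": ["a"], "colony_id": ["c"]}))
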