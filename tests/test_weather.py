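import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoresil import (
    WeatherSeries,
    compute_thi,
    covariate_lag7,
    covariate_on_day,
    match_station,
)

temps = st.floats(min_value=-30, max_value=50)
humidities = st.floats(min_value=0, max_value=100)


@pytest.mark.parametrize(
    "t, rh, expected",
    [
        (14.4, 37.0, 14.4),     # correction term vanishes at T = 14.4
        (30.0, 100.0, 30.0),    # saturated air: THI equals T
        (25.0, 60.0, 22.668),   # hand evaluation: 25 - 0.55*0.4*10.6
    ],
)
def test_thi_values(t, rh, expected):
    assert compute_thi(t, rh) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("t, rh", [(np.nan, 50.0), (20.0, -1.0),
                                   (20.0, 100.5), (np.inf, 50.0)])
def test_thi_rejects_bad_inputs(t, rh):
    with pytest.raises(ValueError):
        compute_thi(t, rh)


@given(t=temps, rh=humidities)
@settings(max_examples=200, deadline=None)
def test_thi_identities(t, rh):
    """THI(T, 100) = T, THI(14.4, RH) = 14.4, and linearity in T."""
    assert compute_thi(t, 100.0) == pytest.approx(t, abs=1e-9)
    assert compute_thi(14.4, rh) == pytest.approx(14.4, abs=1e-9)
    # linear in T at fixed RH: midpoint value is the average
    lo, hi = compute_thi(t, rh), compute_thi(t + 10.0, rh)
    mid = compute_thi(t + 5.0, rh)
    assert mid == pytest.approx(0.5 * (lo + hi), abs=1e-9)


def _series(values, start="2016-01-01"):
    dates = pd.date_range(start, periods=len(values))
    return WeatherSeries("S1", pd.DataFrame(
        {"date": dates, "tavg": values, "rhavg": [50.0] * len(values)}))


def test_series_rejects_duplicate_dates():
    with pytest.raises(ValueError, match="duplicate date"):
        WeatherSeries("S1", pd.DataFrame({
            "date": ["2016-01-01", "2016-01-01"],
            "tavg": [1.0, 2.0], "rhavg": [50.0, 50.0]}))


def test_same_day_lookup_and_missing_marker():
    s = _series([20.0, 21.0, 22.0])
    assert covariate_on_day(s, "2016-01-02") == 21.0
    assert np.isnan(covariate_on_day(s, "2016-02-15"))


def test_lag7_is_mean_of_preceding_week_excluding_test_day():
    # days d-7..d-1 hold 1..7; the test day holds an extreme value that
    # must not contribute
    s = _series([1, 2, 3, 4, 5, 6, 7, 100.0])
    assert covariate_lag7(s, "2016-01-08") == pytest.approx(4.0)


def test_lag7_missing_day_flags_record():
    s = _series([1, 2, 3, 4, 5, 6])  # only 6 preceding days exist
    assert np.isnan(covariate_lag7(s, "2016-01-07"))


@given(st.lists(temps, min_size=7, max_size=7), st.permutations(range(7)))
@settings(max_examples=50, deadline=None)
def test_lag7_permutation_invariant_and_bounded(vals, perm):
    a = covariate_lag7(_series(vals + [0.0]), "2016-01-08")
    b = covariate_lag7(_series([vals[i] for i in perm] + [0.0]), "2016-01-08")
    assert a == pytest.approx(b, abs=1e-9)
    assert min(vals) - 1e-9 <= a <= max(vals) + 1e-9


def test_constant_series_same_day_equals_lag7():
    s = _series([20.0] * 10)
    assert covariate_on_day(s, "2016-01-09") == pytest.approx(
        covariate_lag7(s, "2016-01-09"))


def test_match_station_single_station_and_zero_distance():
    stations = pd.DataFrame({"id": ["S1"], "lat": [40.0], "lon": [22.0]})
    farms = pd.DataFrame({"id": ["F1", "F2"], "lat": [40.0, 41.0],
                          "lon": [22.0, 23.0]})
    out = match_station(farms, stations)
    assert (out["station_id"] == "S1").all()
    assert out.loc[out["farm_id"] == "F1", "distance_km"].iloc[0] == 0.0


def test_match_station_brute_force_three_farms_two_stations():
    stations = pd.DataFrame({"id": ["S1", "S2"], "lat": [0.0, 10.0],
                             "lon": [0.0, 0.0]})
    farms = pd.DataFrame({"id": ["F1", "F2", "F3"],
                          "lat": [1.0, 6.0, 9.0], "lon": [0.0, 0.0, 0.0]})
    out = match_station(farms, stations, metric="euclidean")
    # exhaustive comparison: |1-0|<|1-10|, |6-10|<|6-0|, |9-10|<|9-0|
    assert list(out["station_id"]) == ["S1", "S2", "S2"]


def test_match_station_tie_breaks_on_lowest_id():
    stations = pd.DataFrame({"id": ["S2", "S1"], "lat": [1.0, -1.0],
                             "lon": [0.0, 0.0]})
    farms = pd.DataFrame({"id": ["F1"], "lat": [0.0], "lon": [0.0]})
    out = match_station(farms, stations, metric="euclidean")
    assert out["station_id"].iloc[0] == "S1"


def test_match_station_missing_coordinates_names_farm():
    stations = pd.DataFrame({"id": ["S1"], "lat": [0.0], "lon": [0.0]})
    farms = pd.DataFrame({"id": ["F9"], "lat": [np.nan], "lon": [0.0]})
    with pytest.raises(ValueError, match="F9"):
        match_station(farms, stations)
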