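"""Weather covariates: THI, station matching, same-day and lagged means.

Milk records are matched to the nearest weather station of their farm.
Two covariates per weather variable feed the reaction-norm models: the
value on the test day itself, and the arithmetic mean over the seven
calendar days strictly preceding the test day (the cumulative heat-load
variant).  The temperature-humidity index combines temperature and
relative humidity,

    THI = T - (0.55 * (1 - RH/100)) * (T - 14.4),

so THI equals T at 100% humidity and the correction vanishes at
T = 14.4 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_thi",
    "WeatherSeries",
    "match_station",
    "covariate_on_day",
    "covariate_lag7",
    "attach_covariates",
]

EARTH_RADIUS_KM = 6371.0088


def compute_thi(tavg, rhavg):
    """Temperature-humidity index from daily mean temperature and RH.

    ``rhavg`` must lie in [0, 100] percent and ``tavg`` be finite;
    vectorised over array inputs.
    """
    t = np.asarray(tavg, dtype=float)
    rh = np.asarray(rhavg, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite air temperature")
    if not np.all(np.isfinite(rh)) or np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity outside [0, 100] percent")
    thi = t - (0.55 * (1.0 - rh / 100.0)) * (t - 14.4)
    if np.isscalar(tavg) and np.isscalar(rhavg):
        return float(thi)
    return thi


@dataclass
class WeatherSeries:
    """Daily weather of one station, indexed by date for O(1) lookup."""

    station_id: str
    frame: pd.DataFrame  # columns: date (datetime64), tavg, rhavg, thi

    def __post_init__(self):
        df = self.frame.copy()
        df["date"] = pd.to_datetime(df["date"])
        if df["date"].duplicated().any():
            dup = df.loc[df["date"].duplicated(), "date"].iloc[0]
            raise ValueError(
                f"station {self.station_id}: duplicate date {dup.date()}")
        if "thi" not in df:
            df["thi"] = compute_thi(df["tavg"].to_numpy(),
                                    df["rhavg"].to_numpy())
        self.frame = df.sort_values("date").reset_index(drop=True)
        self._by_date = {d: i for i, d in enumerate(self.frame["date"])}

    def value(self, date, variable: str = "tavg"):
        """Same-day value, or NaN when the date is absent."""
        i = self._by_date.get(pd.Timestamp(date))
        if i is None:
            return float("nan")
        return float(self.frame.loc[i, variable])

    @classmethod
    def from_csv_frame(cls, df: pd.DataFrame) -> dict[str, "WeatherSeries"]:
        """Split a ``station_id,date,tavg,rhavg`` frame into series."""
        return {str(sid): cls(str(sid), sub.drop(columns=["station_id"]))
                for sid, sub in df.groupby("station_id")}


def covariate_on_day(series: WeatherSeries, date, variable: str = "tavg"):
    """Station value on the test day; NaN marks a missing day."""
    return series.value(date, variable)


def covariate_lag7(series: WeatherSeries, date, variable: str = "tavg",
                   window: int = 7):
    """Mean over the ``window`` calendar days strictly preceding ``date``.

    The test day itself is excluded.  If any day of the window is
    missing the result is NaN and the record should be dropped.
    """
    d = pd.Timestamp(date)
    vals = [series.value(d - pd.Timedelta(days=k), variable)
            for k in range(1, window + 1)]
    return float(np.mean(vals))  # NaN propagates if any day is missing


def _great_circle_km(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def match_station(
    farm_coords: pd.DataFrame,
    station_coords: pd.DataFrame,
    metric: str = "great_circle",
) -> pd.DataFrame:
    """Assign every farm to its nearest station.

    Both frames carry ``id, lat, lon`` (for synthetic planar data the
    ``euclidean`` metric treats them as x/y in km).  Ties break on the
    lowest station id; a farm with missing coordinates is an error
    naming the farm.  Returns ``farm_id, station_id, distance_km``.
    """
    if len(station_coords) == 0:
        raise ValueError("no stations with coordinates")
    st = station_coords.sort_values("id", kind="stable")
    rows = []
    for farm in farm_coords.itertuples(index=False):
        if pd.isna(farm.lat) or pd.isna(farm.lon):
            raise ValueError(f"farm {farm.id!r} has no coordinates")
        best = None
        for s in st.itertuples(index=False):
            if metric == "euclidean":
                dist = math.hypot(farm.lat - s.lat, farm.lon - s.lon)
            else:
                dist = _great_circle_km(farm.lat, farm.lon, s.lat, s.lon)
            if best is None or dist < best[1] - 1e-12:
                best = (s.id, dist)
        rows.append({"farm_id": farm.id, "station_id": best[0],
                     "distance_km": best[1]})
    return pd.DataFrame(rows)


def attach_covariates(
    records: pd.DataFrame,
    weather: dict[str, WeatherSeries],
    station_map: pd.DataFrame,
    variables=("tavg", "thi"),
    lag_window: int = 7,
) -> tuple[pd.DataFrame, dict]:
    """Join weather covariates onto test-day records.

    Adds ``<var>`` and ``<var>_lag7`` columns per variable; records whose
    covariates cannot all be resolved are dropped and counted in the
    returned report (the conservative treatment of missing weather).
    """
    sid_of = dict(zip(station_map["farm_id"].astype(str),
                      station_map["station_id"].astype(str)))
    out = records.copy()
    out["test_date"] = pd.to_datetime(out["test_date"])
    for var in variables:
        same, lag = [], []
        for rec in out.itertuples(index=False):
            sid = sid_of.get(str(rec.flock_id))
            if sid is None or sid not in weather:
                same.append(float("nan"))
                lag.append(float("nan"))
                continue
            series = weather[sid]
            same.append(covariate_on_day(series, rec.test_date, var))
            lag.append(covariate_lag7(series, rec.test_date, var,
                                      window=lag_window))
        out[var] = same
        out[f"{var}_lag7"] = lag
    cov_cols = [c for v in variables for c in (v, f"{v}_lag7")]
    ok = out[cov_cols].notna().all(axis=1)
    report = {"n_input": int(len(out)),
              "n_dropped_missing_weather": int((~ok).sum()),
              "n_output": int(ok.sum())}
    return out[ok].reset_index(drop=True), report
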