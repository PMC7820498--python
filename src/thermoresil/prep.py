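"""Test-day record edits, lambing seasons and lifetime milk yield.

Three sequential edits clean the raw test-day data:

1. drop records taken fewer than 42 days after lambing (lambs suckle
   until day 42, milking starts afterwards);
2. within each month-of-lactation group, drop records farther than four
   sample standard deviations from the group mean (group statistics
   computed once, on the data surviving step 1; groups with fewer than
   three records are exempt);
3. drop every record of animals left with fewer than three records over
   their productive life.

Lambing seasons follow the calendar: autumn = September-November
lambings, winter = December-February, spring = March-May; June-August
lambings fall outside the study design and are excluded.

Lifetime milk yield accumulates each lactation with the Fleischmann
test-interval method (first interval credited at the first test's yield,
interior intervals at interval-midpoint average, a short tail after the
last test at the last yield) and sums an animal's lactations within each
lambing season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "assign_season",
    "edit_records",
    "lifetime_milk",
    "lifetime_table",
    "EditReport",
]

SEASON_OF_MONTH = {9: "autumn", 10: "autumn", 11: "autumn",
                   12: "winter", 1: "winter", 2: "winter",
                   3: "spring", 4: "spring", 5: "spring"}

#: average days per month used to bin days-in-milk into lactation months
DAYS_PER_MONTH = 30.44

#: Fleischmann tail credited after the last test, and the total-DIM cap
DEFAULT_TAIL_DAYS = 15
MAX_LACTATION_DIM = 210


@dataclass
class EditReport:
    n_input: int = 0
    n_dim_filter: int = 0
    n_sd_filter: int = 0
    n_minrecords_filter: int = 0
    n_output: int = 0

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def assign_season(lambing_date) -> str | None:
    """Calendar season of a lambing date; None for June-August lambings."""
    month = pd.Timestamp(lambing_date).month
    return SEASON_OF_MONTH.get(month)


def month_of_lactation(dim) -> np.ndarray:
    """1-based month within the lactation from days in milk."""
    return (np.asarray(dim, dtype=float) // DAYS_PER_MONTH).astype(int) + 1


def edit_records(
    records: pd.DataFrame,
    sd_threshold: float = 4.0,
    min_dim: int = 42,
    min_records: int = 3,
    sd_within_flock: bool = False,
) -> tuple[pd.DataFrame, EditReport]:
    """Apply the three sequential data edits; returns (retained, report).

    The 4-SD screen pools flocks within month-of-lactation by default
    (``sd_within_flock=True`` groups by flock as well).  Filters are
    applied once, in order, without re-computing group statistics after
    removals.
    """
    report = EditReport(n_input=len(records))
    if len(records) == 0:
        return records.copy(), report
    df = records.copy()

    keep1 = df["dim"] >= min_dim
    report.n_dim_filter = int((~keep1).sum())
    df = df[keep1]

    grp_cols = ["_lac_month"] + (["flock_id"] if sd_within_flock else [])
    df = df.assign(_lac_month=month_of_lactation(df["dim"]))
    g = df.groupby(grp_cols)["milk_kg"]
    mean = g.transform("mean")
    sd = g.transform("std")  # sample SD (ddof=1); NaN for n=1 groups
    n = g.transform("size")
    dev = (df["milk_kg"] - mean).abs()
    keep2 = (n < 3) | sd.isna() | (sd == 0) | (dev <= sd_threshold * sd)
    report.n_sd_filter = int((~keep2).sum())
    df = df[keep2].drop(columns="_lac_month")

    counts = df.groupby("animal_id")["milk_kg"].transform("size")
    keep3 = counts >= min_records
    report.n_minrecords_filter = int((~keep3).sum())
    df = df[keep3]

    report.n_output = len(df)
    return df.reset_index(drop=True), report


def fleischmann_yield(
    dims: np.ndarray,
    yields: np.ndarray,
    tail_days: int = DEFAULT_TAIL_DAYS,
    max_dim: int = MAX_LACTATION_DIM,
) -> tuple[float, int]:
    """Test-interval milk yield of one lactation; returns (kg, total days).

    ``dims`` are days in milk at each test, sorted ascending.  The first
    interval spans lambing to the first test at that test's daily yield;
    interior intervals use the average of their bounding tests; the tail
    extends ``tail_days`` past the last test, capped so the credited
    lactation length does not exceed ``max_dim`` days.
    """
    order = np.argsort(dims)
    d = np.asarray(dims, dtype=float)[order]
    y = np.asarray(yields, dtype=float)[order]
    total = d[0] * y[0]
    for i in range(1, len(d)):
        total += (d[i] - d[i - 1]) * 0.5 * (y[i] + y[i - 1])
    tail = min(tail_days, max(0, max_dim - int(d[-1])))
    total += tail * y[-1]
    return float(total), int(d[-1]) + tail


def lifetime_milk(
    records: pd.DataFrame,
    tail_days: int = DEFAULT_TAIL_DAYS,
    max_dim: int = MAX_LACTATION_DIM,
) -> pd.DataFrame:
    """Total lifetime milk per animal x lambing season.

    One lactation = one (animal, lambing_date) pair; its season follows
    the lambing month.  An animal lambing in the same season of
    different years accumulates those lactations into one row.  Records
    of June-August lambings are excluded entirely.  Returns
    ``animal_id, season, lifetime_milk_kg, total_dim, total_lactations``.
    """
    df = records.copy()
    df["season"] = pd.to_datetime(df["lambing_date"]).map(assign_season)
    df = df[df["season"].notna()]
    rows = []
    for (animal, season), sub in df.groupby(["animal_id", "season"]):
        total_kg, total_dim, n_lact = 0.0, 0, 0
        for _, lact in sub.groupby("lambing_date"):
            kg, days = fleischmann_yield(
                lact["dim"].to_numpy(), lact["milk_kg"].to_numpy(),
                tail_days=tail_days, max_dim=max_dim)
            total_kg += kg
            total_dim += days
            n_lact += 1
        rows.append({"animal_id": animal, "season": season,
                     "lifetime_milk_kg": total_kg, "total_dim": total_dim,
                     "total_lactations": n_lact})
    return pd.DataFrame(
        rows, columns=["animal_id", "season", "lifetime_milk_kg",
                       "total_dim", "total_lactations"])


def lifetime_table(records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Lifetime yields plus first-lambing context used as fixed effects."""
    lt = lifetime_milk(records, **kwargs)
    df = records.copy()
    df["lambing_date"] = pd.to_datetime(df["lambing_date"])
    first = (df.sort_values("lambing_date")
               .groupby("animal_id")
               .agg(flock_id=("flock_id", "first"),
                    first_lambing=("lambing_date", "first"))
               .reset_index())
    first["first_lambing_year"] = first["first_lambing"].dt.year
    first["first_lambing_month"] = first["first_lambing"].dt.month
    return lt.merge(first.drop(columns="first_lambing"), on="animal_id")
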