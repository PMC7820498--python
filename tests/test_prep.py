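import numpy as np
import pandas as pd
import pytest

from thermoresil import assign_season, edit_records, lifetime_milk
from thermoresil.prep import fleischmann_yield


@pytest.mark.parametrize("date, season", [
    ("2015-10-15", "autumn"), ("2015-09-01", "autumn"),
    ("2015-11-30", "autumn"),
    ("2016-01-03", "winter"), ("2015-12-01", "winter"),
    ("2016-02-29", "winter"),
    ("2016-03-01", "spring"), ("2016-05-31", "spring"),
    ("2016-07-01", None), ("2016-06-15", None), ("2016-08-31", None),
])
def test_assign_season_calendar_windows(date, season):
    assert assign_season(date) == season


def _frame(rows):
    return pd.DataFrame(rows, columns=["animal_id", "flock_id", "dim",
                                       "milk_kg"])


def _brute_force_edits(df, min_dim=42, sd_k=4.0, min_rec=3):
    """Literal re-application of the three rules, loops and all."""
    df = df[df["dim"] >= min_dim].copy()
    month = (df["dim"] // 30.44).astype(int) + 1
    keep = []
    for i in df.index:
        grp = df[month == month[i]]["milk_kg"]
        if len(grp) < 3 or grp.std(ddof=1) == 0:
            keep.append(i)
        elif abs(df.loc[i, "milk_kg"] - grp.mean()) <= sd_k * grp.std(ddof=1):
            keep.append(i)
    df = df.loc[keep]
    counts = df["animal_id"].value_counts()
    return df[df["animal_id"].map(counts) >= min_rec]


def test_dim_filter_boundary():
    df = _frame([("a", "F", 41, 2.0), ("a", "F", 42, 2.0),
                 ("a", "F", 80, 2.0), ("a", "F", 110, 2.0)])
    out, rep = edit_records(df)
    assert rep.n_dim_filter == 1
    assert 41 not in out["dim"].values and 42 in out["dim"].values


def test_planted_outlier_removed_by_sd_rule():
    rng = np.random.default_rng(42)
    rows = []
    for i in range(5):  # 5 animals x 4 records in one lactation month band
        for j in range(4):
            rows.append((f"a{i}", "F", 50 + j, float(rng.normal(2.0, 0.05))))
    rows[7] = ("a1", "F", 57, 25.0)  # grossly extreme value
    df = _frame(rows)
    out, rep = edit_records(df)
    expected = _brute_force_edits(df)
    assert rep.n_sd_filter == 1
    assert len(out) == len(expected) == 19
    pd.testing.assert_frame_equal(out.sort_values(["animal_id", "dim"],
                                                  ignore_index=True),
                                  expected.sort_values(["animal_id", "dim"],
                                                       ignore_index=True))


def test_exactly_three_records_retained():
    df = _frame([("keep", "F", d, 2.0) for d in (42, 72, 102)]
                + [("drop", "F", d, 2.0) for d in (42, 72)])
    out, rep = edit_records(df)
    assert set(out["animal_id"]) == {"keep"}
    assert rep.n_minrecords_filter == 2


def test_edit_report_counts_are_consistent_and_idempotent():
    rng = np.random.default_rng(3)
    rows = [(f"a{rng.integers(8)}", "F", int(rng.integers(10, 200)),
             float(rng.normal(2.0, 0.4))) for _ in range(120)]
    df = _frame(rows)
    out, rep = edit_records(df)
    assert rep.n_input - rep.n_output == (
        rep.n_dim_filter + rep.n_sd_filter + rep.n_minrecords_filter)
    assert set(map(tuple, out.values)) <= set(map(tuple, df.values))
    again, rep2 = edit_records(out)
    pd.testing.assert_frame_equal(again, out)
    assert rep2.n_dim_filter == rep2.n_sd_filter == 0
    assert rep2.n_minrecords_filter == 0


def test_empty_input_gives_zeroed_report():
    out, rep = edit_records(_frame([]))
    assert len(out) == 0
    assert rep.to_dict() == {"n_input": 0, "n_dim_filter": 0,
                             "n_sd_filter": 0, "n_minrecords_filter": 0,
                             "n_output": 0}


@pytest.mark.parametrize("dims, yields, tail, expected", [
    ([50], [2.0], 15, 130.0),            # 50*2 + 15*2
    ([50, 80], [2.0, 1.0], 15, 160.0),   # 100 + 30*1.5 + 15*1
])
def test_fleischmann_hand_values(dims, yields, tail, expected):
    kg, _ = fleischmann_yield(np.array(dims), np.array(yields),
                              tail_days=tail)
    assert kg == pytest.approx(expected)


def test_fleischmann_tail_capped_at_max_dim():
    kg, days = fleischmann_yield(np.array([205]), np.array([1.0]),
                                 tail_days=15, max_dim=210)
    assert days == 210 and kg == pytest.approx(205 + 5)


def _lact(animal, lamb, dims, yields):
    return pd.DataFrame({
        "animal_id": animal, "flock_id": "F",
        "lambing_date": lamb, "dim": dims, "milk_kg": yields})


def test_lifetime_sums_repeat_lambings_in_same_season():
    df = pd.concat([
        _lact("e", "2015-10-01", [50], [2.0]),
        _lact("e", "2016-10-20", [50], [2.0]),
    ])
    out = lifetime_milk(df)
    assert len(out) == 1
    row = out.iloc[0]
    assert row["season"] == "autumn"
    assert row["lifetime_milk_kg"] == pytest.approx(2 * 130.0)
    assert row["total_lactations"] == 2


def test_lifetime_excludes_summer_lambings_and_scales_linearly():
    df = pd.concat([
        _lact("e", "2016-07-01", [50], [2.0]),   # June-August: excluded
        _lact("e", "2016-12-05", [50, 80], [2.0, 1.0]),
    ])
    out = lifetime_milk(df)
    assert list(out["season"]) == ["winter"]
    doubled = df.copy()
    doubled["milk_kg"] *= 2
    out2 = lifetime_milk(doubled)
    assert out2["lifetime_milk_kg"].iloc[0] == pytest.approx(
        2 * out["lifetime_milk_kg"].iloc[0])
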