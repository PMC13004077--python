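"""Wear-metric derivation vs independent brute-force recounts."""

import numpy as np
import pandas as pd
import pytest

from weartime import (
    build_person_days,
    daily_wear_hours,
    regroup_small_categories,
    summarize_cohort,
    summarize_person,
)
from weartime.exceptions import DataIntegrityError, JoinError

from conftest import random_step_table


def oracle_recount(steps):
    """Brute-force per-(person, day) recount of wear hours and totals."""
    acc = {}
    for r in steps.itertuples(index=False):
        key = (r.person_id, pd.Timestamp(r.date).normalize())
        wear, total = acc.get(key, (0, 0))
        acc[key] = (wear + (1 if r.steps > 0 else 0), total + r.steps)
    return acc


def oracle_summary(steps, pid):
    """Brute-force person summary straight from raw records."""
    recount = {d: v for (p, d), v in oracle_recount(steps).items() if p == pid}
    first, last = min(recount), max(recount)
    span = (last - first).days + 1
    worn_days = [d for d, (w, _) in recount.items() if w >= 1]
    return {
        "span_days": span,
        "days_worn": len(worn_days),
        "pct_days_worn": 100 * len(worn_days) / span,
        "mean_daily_wear_hours": (
            np.mean([recount[d][0] for d in worn_days]) if worn_days else np.nan
        ),
    }


def test_daily_wear_hours_counts_nonzero_hours():
    day = pd.DataFrame({"hour": [7, 8, 9, 22], "steps": [120, 0, 35, 500]})
    assert daily_wear_hours(day) == 3
    all_zero = pd.DataFrame({"hour": range(24), "steps": [0] * 24})
    assert daily_wear_hours(all_zero) == 0


def test_daily_wear_hours_rejects_duplicate_hours():
    day = pd.DataFrame({"hour": [7, 7], "steps": [10, 20]})
    with pytest.raises(DataIntegrityError):
        daily_wear_hours(day)


def test_build_person_days_materializes_span():
    steps = pd.DataFrame(
        {
            "person_id": ["a", "a"],
            "date": pd.to_datetime(["2020-01-01", "2020-01-03"]),
            "hour": [9, 10],
            "steps": [100, 200],
        }
    )
    participants = pd.DataFrame({"person_id": ["a"], "group": ["case"]})
    days = build_person_days(steps, participants)
    assert len(days) == 3
    mid = days[days["date"] == pd.Timestamp("2020-01-02")].iloc[0]
    assert mid["wear_hours"] == 0 and mid["total_steps"] == 0
    assert np.isnan(mid["steps_per_hour"])
    assert (days["group"] == "case").all()


def test_build_person_days_empty_input():
    steps = pd.DataFrame(columns=["person_id", "date", "hour", "steps"])
    participants = pd.DataFrame({"person_id": ["a"], "group": ["case"]})
    assert len(build_person_days(steps, participants)) == 0


def test_build_person_days_rejects_orphans_and_duplicates():
    participants = pd.DataFrame({"person_id": ["a"], "group": ["case"]})
    orphan = pd.DataFrame(
        {"person_id": ["zz"], "date": [pd.Timestamp("2020-01-01")], "hour": [1], "steps": [5]}
    )
    with pytest.raises(JoinError, match="zz"):
        build_person_days(orphan, participants)
    dup = pd.DataFrame(
        {
            "person_id": ["a", "a"],
            "date": [pd.Timestamp("2020-01-01")] * 2,
            "hour": [1, 1],
            "steps": [5, 6],
        }
    )
    with pytest.raises(DataIntegrityError):
        build_person_days(dup, participants)


def test_recount_matches_oracle_on_random_tables(rng):
    for _ in range(25):
        steps, participants = random_step_table(rng)
        if len(steps) == 0:
            continue
        days = build_person_days(steps, participants)
        oracle = oracle_recount(steps)
        recorded = days[days["wear_hours"] + days["total_steps"] > 0]
        for r in recorded.itertuples(index=False):
            w, t = oracle.get((r.person_id, r.date), (0, 0))
            assert (r.wear_hours, r.total_steps) == (w, t)
        # every oracle day present in the person-day table
        got = {(r.person_id, r.date) for r in days.itertuples(index=False)}
        assert set(oracle) <= got


def test_summaries_match_oracle_on_random_tables(rng):
    for _ in range(15):
        steps, participants = random_step_table(rng)
        if len(steps) == 0:
            continue
        days = build_person_days(steps, participants)
        summary = summarize_cohort(days).set_index("person_id")
        for pid in steps["person_id"].unique():
            want = oracle_summary(steps, pid)
            got = summary.loc[pid]
            assert got["span_days"] == want["span_days"]
            assert got["days_worn"] == want["days_worn"]
            assert got["pct_days_worn"] == pytest.approx(want["pct_days_worn"])
            if want["days_worn"]:
                assert got["mean_daily_wear_hours"] == pytest.approx(
                    want["mean_daily_wear_hours"]
                )


def test_two_day_wearer_shows_full_wear_but_ineligible():
    """Two days of data, both worn: 100% wear time, yet below the 30-day rule."""
    days = pd.DataFrame(
        {
            "person_id": ["a", "a"],
            "date": pd.to_datetime(["2020-01-01", "2020-01-02"]),
            "wear_hours": [5, 8],
            "total_steps": [500, 800],
        }
    )
    s = summarize_person(days)
    assert s["pct_days_worn"] == 100.0
    assert s["span_days"] == 2
    assert not s["eligible"]


def test_summary_conventions():
    dates = pd.date_range("2020-01-01", "2020-01-10")
    wear = [3, 0, 5, 0, 2, 0, 1, 0, 4, 0]  # worn on 5 of 10 span days
    days = pd.DataFrame(
        {"person_id": "a", "date": dates, "wear_hours": wear, "total_steps": [w * 10 for w in wear]}
    )
    s = summarize_person(days)
    assert s["pct_days_worn"] == 50.0
    three = pd.DataFrame(
        {
            "person_id": "b",
            "date": pd.date_range("2020-01-01", periods=3),
            "wear_hours": [10, 12, 0],
            "total_steps": [100, 120, 0],
        }
    )
    assert summarize_person(three)["mean_daily_wear_hours"] == 11.0


def test_zero_step_record_changes_nothing():
    steps, participants = random_step_table(np.random.default_rng(5))
    days = build_person_days(steps, participants)
    extra_row = steps.iloc[[0]].copy()
    used = set(
        zip(steps["person_id"], steps["date"], steps["hour"])
    )
    for h in range(24):
        if (extra_row.iloc[0]["person_id"], extra_row.iloc[0]["date"], h) not in used:
            extra_row["hour"] = h
            break
    extra_row["steps"] = 0
    days2 = build_person_days(pd.concat([steps, extra_row], ignore_index=True), participants)
    pd.testing.assert_frame_equal(
        days.sort_values(["person_id", "date"]).reset_index(drop=True),
        days2.sort_values(["person_id", "date"]).reset_index(drop=True),
    )


def test_metrics_invariant_to_row_order(rng):
    steps, participants = random_step_table(rng)
    days1 = build_person_days(steps, participants)
    shuffled = steps.sample(frac=1.0, random_state=1).reset_index(drop=True)
    days2 = build_person_days(shuffled, participants)
    key = ["person_id", "date"]
    pd.testing.assert_frame_equal(
        days1.sort_values(key).reset_index(drop=True),
        days2.sort_values(key).reset_index(drop=True),
    )


@pytest.mark.parametrize("n_members,changed", [(19, True), (20, False)])
def test_regroup_threshold_boundary(n_members, changed):
    parts = pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(n_members + 25)],
            "group": "control",
            "race_ethnicity": ["small"] * n_members + ["big"] * 25,
        }
    )
    out = regroup_small_categories(parts, "race_ethnicity", min_n=20, other_label="other")
    assert ("small" not in set(out["race_ethnicity"])) == changed
    assert (out["race_ethnicity"] == "big").sum() == 25


def test_regroup_identity_and_idempotence():
    parts = pd.DataFrame(
        {
            "person_id": [f"p{i}" for i in range(40)],
            "race_ethnicity": ["a"] * 20 + ["b"] * 20,
        }
    )
    out = regroup_small_categories(parts, "race_ethnicity", min_n=20)
    pd.testing.assert_frame_equal(out, parts)
    # pooled label exempt even while still small
    small = pd.DataFrame(
        {"person_id": [f"p{i}" for i in range(10)], "race_ethnicity": ["x"] * 4 + ["y"] * 6}
    )
    once = regroup_small_categories(small, "race_ethnicity", min_n=20, other_label="other")
    twice = regroup_small_categories(once, "race_ethnicity", min_n=20, other_label="other")
    assert (once["race_ethnicity"] == "other").all()
    pd.testing.assert_frame_equal(once, twice)
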