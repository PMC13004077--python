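"""Wear-time metrics derived from intraday step records.

Two metrics drive everything downstream:

* **daily wear hours** — the number of hours in a day with a non-zero
  step count (step-based wear detection; sedentary worn hours with zero
  steps are invisible to it);
* **percentage of days worn** — days with any non-zero step data divided
  by the inclusive span between a person's first and last day of data.

The working grain is the *person-day*: one row per participant per
calendar day of their span, with days lacking any record materialized as
zero-wear days so that retention accounting can see the full observation
window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError, JoinError, WeartimeError

__all__ = [
    "daily_wear_hours",
    "build_person_days",
    "summarize_person",
    "summarize_cohort",
    "regroup_small_categories",
]

#: participant columns that are identity/bookkeeping, not adjustment covariates
NON_COVARIATE_COLUMNS = ("person_id", "group", "index_date", "diagnosis_date")


def _check_no_duplicate_hours(steps: pd.DataFrame) -> None:
    dup = steps.duplicated(subset=["person_id", "date", "hour"])
    if dup.any():
        bad = steps.loc[dup, ["person_id", "date", "hour"]].head(5)
        raise DataIntegrityError(
            f"duplicate (person_id, date, hour) records, e.g.:\n{bad.to_string(index=False)}"
        )


def daily_wear_hours(day_records: pd.DataFrame) -> int:
    """Wear hours for a single person-day: count of hours with steps > 0.

    ``day_records`` must contain the columns ``hour`` and ``steps`` for one
    (person, date); duplicated hours raise :class:`DataIntegrityError`.
    """
    if day_records["hour"].duplicated().any():
        raise DataIntegrityError("duplicate hour within one person-day")
    return int((day_records["steps"] > 0).sum())


def build_person_days(steps: pd.DataFrame, participants: pd.DataFrame) -> pd.DataFrame:
    """Aggregate hourly step records into the person-day table.

    One output row per (person, calendar day) in each person's inclusive
    first-to-last-day span; days without any record appear with
    ``wear_hours = 0`` and ``total_steps = 0``. Group and covariates are
    joined from ``participants``. ``steps_per_hour`` is NaN on zero-wear
    days. Persons with no step records at all contribute no rows (their
    span is undefined).
    """
    required = {"person_id", "date", "hour", "steps"}
    missing = required - set(steps.columns)
    if missing:
        raise WeartimeError(f"step table missing columns: {sorted(missing)}")
    orphans = set(steps["person_id"]) - set(participants["person_id"])
    if orphans:
        raise JoinError(orphans)
    _check_no_duplicate_hours(steps)

    if len(steps) == 0:
        empty = pd.DataFrame(
            {
                "person_id": pd.Series(dtype="object"),
                "date": pd.Series(dtype="datetime64[ns]"),
                "wear_hours": pd.Series(dtype="int64"),
                "total_steps": pd.Series(dtype="int64"),
                "steps_per_hour": pd.Series(dtype="float64"),
            }
        )
        return empty.merge(participants.drop(columns=["index_date"], errors="ignore"), on="person_id", how="left")

    steps = steps.copy()
    steps["date"] = pd.to_datetime(steps["date"]).dt.normalize()
    daily = (
        steps.assign(worn=steps["steps"] > 0)
        .groupby(["person_id", "date"], sort=True)
        .agg(wear_hours=("worn", "sum"), total_steps=("steps", "sum"))
        .reset_index()
    )

    # materialize each person's full inclusive span
    bounds = daily.groupby("person_id")["date"].agg(["min", "max"])
    n_days = ((bounds["max"] - bounds["min"]).dt.days + 1).to_numpy()
    pid_grid = np.repeat(bounds.index.to_numpy(), n_days)
    offsets = np.concatenate([np.arange(n) for n in n_days]) if len(n_days) else np.array([], dtype=int)
    date_grid = np.repeat(bounds["min"].to_numpy(), n_days) + offsets * np.timedelta64(1, "D")
    grid = pd.DataFrame({"person_id": pid_grid, "date": date_grid})

    out = grid.merge(daily, on=["person_id", "date"], how="left")
    out["wear_hours"] = out["wear_hours"].fillna(0).astype("int64")
    out["total_steps"] = out["total_steps"].fillna(0).astype("int64")
    out["steps_per_hour"] = np.where(
        out["wear_hours"] > 0, out["total_steps"] / out["wear_hours"].replace(0, 1), np.nan
    )
    out = out.merge(
        participants.drop(columns=["index_date"], errors="ignore"), on="person_id", how="left"
    )
    return out


def summarize_person(person_days: pd.DataFrame, min_days: int = 30) -> dict:
    """Per-person wear summary from that person's person-day rows.

    ``span_days`` is the inclusive span ``(last − first) + 1``; a day counts
    as worn when it has at least one non-zero-step hour; the mean daily wear
    hours averages over worn days only (the intensive margin, kept separate
    from the extensive margin of how many days were worn at all).
    ``eligible`` applies the minimum-days-of-data rule (default 30 worn
    days), guarding against misleading percentages from very short records
    — e.g. two days of data, both worn, reads as 100% wear time.
    """
    if len(person_days) == 0:
        raise WeartimeError("summarize_person: empty person-day input")
    pids = person_days["person_id"].unique()
    if len(pids) != 1:
        raise WeartimeError(f"summarize_person expects one person, got {len(pids)}")
    first = person_days["date"].min()
    last = person_days["date"].max()
    span = int((last - first).days) + 1
    worn = person_days["wear_hours"] >= 1
    days_worn = int(worn.sum())
    mean_wear = float(person_days.loc[worn, "wear_hours"].mean()) if days_worn else float("nan")
    return {
        "person_id": pids[0],
        "first_day": first,
        "last_day": last,
        "span_days": span,
        "days_worn": days_worn,
        "pct_days_worn": 100.0 * days_worn / span,
        "mean_daily_wear_hours": mean_wear,
        "eligible": days_worn >= min_days,
    }


def summarize_cohort(person_days: pd.DataFrame, min_days: int = 30) -> pd.DataFrame:
    """Vectorized :func:`summarize_person` across a cohort (one row per person)."""
    if len(person_days) == 0:
        return pd.DataFrame(
            columns=[
                "person_id",
                "first_day",
                "last_day",
                "span_days",
                "days_worn",
                "pct_days_worn",
                "mean_daily_wear_hours",
                "eligible",
            ]
        )
    g = person_days.assign(
        worn=person_days["wear_hours"] >= 1,
        worn_hours_on_worn=np.where(
            person_days["wear_hours"] >= 1, person_days["wear_hours"], np.nan
        ),
    ).groupby("person_id", sort=True)
    out = g.agg(
        first_day=("date", "min"),
        last_day=("date", "max"),
        days_worn=("worn", "sum"),
        mean_daily_wear_hours=("worn_hours_on_worn", "mean"),
    ).reset_index()
    out["span_days"] = (out["last_day"] - out["first_day"]).dt.days + 1
    out["pct_days_worn"] = 100.0 * out["days_worn"] / out["span_days"]
    out["eligible"] = out["days_worn"] >= min_days
    return out[
        [
            "person_id",
            "first_day",
            "last_day",
            "span_days",
            "days_worn",
            "pct_days_worn",
            "mean_daily_wear_hours",
            "eligible",
        ]
    ]


def regroup_small_categories(
    participants: pd.DataFrame,
    column: str,
    min_n: int = 20,
    other_label: str = "other",
) -> pd.DataFrame:
    """Pool categories with fewer than ``min_n`` participants into ``other_label``.

    The privacy-motivated small-cell rule: any category of ``column`` with
    fewer than ``min_n`` members is relabeled. The pooled label itself is
    exempt from further regrouping (so one pass is idempotent even when the
    pooled cell remains small). Categories at or above the threshold are
    untouched.
    """
    if column not in participants.columns:
        raise WeartimeError(f"regroup_small_categories: no column '{column}'")
    counts = participants[column].value_counts()
    small = {c for c, n in counts.items() if n < min_n and c != other_label}
    if not small:
        return participants
    out = participants.copy()
    out[column] = out[column].where(~out[column].isin(small), other_label)
    return out


def covariate_columns(participants: pd.DataFrame) -> list[str]:
    """Names of the adjustment covariate columns in a participant table."""
    return [c for c in participants.columns if c not in NON_COVARIATE_COLUMNS]
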