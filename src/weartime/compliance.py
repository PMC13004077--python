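"""Day-level compliance criteria and per-group retention accounting.

The classical validity rule for a day of step data is at least 10 hours of
wear plus plausibility bounds on the daily total (more than 100 steps,
fewer than 45,000). Because wear propensity differs between clinical
groups, this filter excludes days *differentially* — the retention report
quantifies exactly how much data each group loses, which is the headline
selection-bias statistic of the framework.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import pandas as pd

from .exceptions import ConfigurationError, WeartimeError

__all__ = ["ComplianceConfig", "RetentionReport", "apply_compliance", "retention_diff"]


@dataclass(frozen=True)
class ComplianceConfig:
    """Boundary semantics are literal: wear hours inclusive (>=), step bounds strict (>, <).

    A day with exactly 100 steps or exactly 45,000 steps is excluded; a day
    with exactly ``min_wear_hours`` hours is retained.
    """

    min_wear_hours: float = 10.0
    min_steps: float = 100.0
    max_steps: float = 45_000.0

    def __post_init__(self):
        if not (0 <= self.min_wear_hours <= 24):
            raise ConfigurationError("min_wear_hours", "must lie in [0, 24]")
        if not self.min_steps < self.max_steps:
            raise ConfigurationError("min_steps", "must be < max_steps")

    @classmethod
    def identity(cls) -> "ComplianceConfig":
        """A config that retains every person-day."""
        return cls(min_wear_hours=0.0, min_steps=-1.0, max_steps=math.inf)


@dataclass
class GroupRetention:
    total_days: int
    retained_days: int
    unique_participants: int

    @property
    def retained_pct(self) -> float:
        return 100.0 * self.retained_days / self.total_days if self.total_days else float("nan")


@dataclass
class RetentionReport:
    """Per-method, per-group accounting of person-days kept vs excluded.

    Zero-wear days materialized within a person's span count in
    ``total_days``: retention percentages are fractions of the full
    observation window, so an all-days method reads 100%.
    """

    method: str
    groups: dict[str, GroupRetention] = field(default_factory=dict)

    @property
    def total_days(self) -> int:
        return sum(g.total_days for g in self.groups.values())

    @property
    def retained_days(self) -> int:
        return sum(g.retained_days for g in self.groups.values())

    @property
    def retained_pct(self) -> float:
        return 100.0 * self.retained_days / self.total_days if self.total_days else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": self.method,
                "group": name,
                "total_days": g.total_days,
                "retained_days": g.retained_days,
                "retained_pct": g.retained_pct,
                "unique_participants": g.unique_participants,
            }
            for name, g in self.groups.items()
        ]
        rows.append(
            {
                "method": self.method,
                "group": "overall",
                "total_days": self.total_days,
                "retained_days": self.retained_days,
                "retained_pct": self.retained_pct,
                "unique_participants": sum(g.unique_participants for g in self.groups.values()),
            }
        )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "groups": {
                name: {**asdict(g), "retained_pct": g.retained_pct}
                for name, g in self.groups.items()
            },
            "overall": {
                "total_days": self.total_days,
                "retained_days": self.retained_days,
                "retained_pct": self.retained_pct,
            },
        }


def _report_from_mask(person_days: pd.DataFrame, mask: pd.Series, method: str) -> RetentionReport:
    report = RetentionReport(method=method)
    for name, sub in person_days.groupby("group", sort=True, observed=True):
        kept = mask.loc[sub.index]
        report.groups[str(name)] = GroupRetention(
            total_days=int(len(sub)),
            retained_days=int(kept.sum()),
            unique_participants=int(sub.loc[kept, "person_id"].nunique()),
        )
    return report


def apply_compliance(
    person_days: pd.DataFrame,
    config: ComplianceConfig | None = None,
    method: str = "standard",
) -> tuple[pd.DataFrame, RetentionReport]:
    """Retain person-days meeting the compliance criteria; tally per group.

    A day is retained iff ``wear_hours >= min_wear_hours`` and
    ``min_steps < total_steps < max_steps``.
    """
    config = config or ComplianceConfig()
    mask = (
        (person_days["wear_hours"] >= config.min_wear_hours)
        & (person_days["total_steps"] > config.min_steps)
        & (person_days["total_steps"] < config.max_steps)
    )
    report = _report_from_mask(person_days, mask, method)
    return person_days[mask].copy(), report


def retention_diff(report: RetentionReport) -> dict[tuple[str, str], float]:
    """Percentage-point retention gaps for every ordered group pair.

    The value under key ``(a, b)`` is ``retained_pct(a) − retained_pct(b)``:
    positive means group *a* kept a larger share of its days than group *b*
    (i.e. the filter bore harder on *b*).
    """
    names = list(report.groups)
    if len(names) < 2:
        raise WeartimeError("retention_diff requires at least two groups")
    return {
        (a, b): report.groups[a].retained_pct - report.groups[b].retained_pct
        for a in names
        for b in names
        if a != b
    }
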