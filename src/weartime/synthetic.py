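"""Synthetic wearable-step cohort generator with known ground truth.

Emulates the structure of bring-your-own-device intraday Fitbit step data:
persons observed over a multi-month span, hourly step counts, and --
crucially for studying wear-time bias -- *group-dependent wear propensity*
(cases wear the device fewer hours) alongside *group-dependent activity
rate* (cases take fewer steps per worn hour). Because both channels differ
between groups, naive compliance filtering confounds device exposure with
the activity signal, which is exactly the failure mode the bias-handling
methods in :mod:`weartime.bias` are designed to expose.

Generative model
----------------
For person *i* in group *g*, each hour of each day is independently worn
with probability ``expit(logit(wear_prob_g) + u_i + drop_g·post)`` where
``u_i ~ N(0, person_sd_wear)`` and ``drop_g`` is an additive log-odds shift
applied from the cohort index day onward. Each worn hour receives a step
count drawn ``Poisson(max(0, rate_g + v_i))`` with ``v_i ~ N(0,
person_sd_rate)``. Worn hours with a Poisson draw of zero are emitted as
present-but-zero records: downstream wear detection counts only non-zero
hours, deliberately reproducing the known limitation that sedentary worn
time is invisible to step-based wear estimation.

Unworn hours are simply absent from the step table. Daily wear hours are
therefore integers 0--24 by construction, matching the downstream metric.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import ConfigurationError
from .io import read_config_file

__all__ = ["CohortConfig", "generate_cohort", "truth_summary", "write_cohort"]

CASE = "case"
CONTROL = "control"

#: default categorical covariate distributions (independent of group);
#: loosely mirror the skew of a volunteer bring-your-own-device cohort
DEFAULT_COVARIATES: dict[str, dict[str, float]] = {
    "age_band": {"<40": 0.30, "40-60": 0.40, "60+": 0.30},
    "sex": {"female": 0.60, "male": 0.38, "other": 0.02},
    "race_ethnicity": {
        "white_nh": 0.70,
        "black_nh": 0.10,
        "hispanic": 0.10,
        "asian_nh": 0.05,
        "other_nh": 0.05,
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults encode the confounded study condition used throughout the
    validation suite: cases both wear the device less (0.45 vs 0.75
    per-hour wear propensity, i.e. 10.8 vs 18.0 expected daily wear hours)
    and step less per worn hour (40 vs 50).
    """

    n_cases: int = 100
    n_controls: int = 100
    n_days: int = 180
    wear_prob_case: float = 0.45
    wear_prob_control: float = 0.75
    rate_case: float = 40.0
    rate_control: float = 50.0
    person_sd_wear: float = 0.0
    person_sd_rate: float = 0.0
    post_index_wear_drop_case: float = 0.0
    post_index_wear_drop_control: float = 0.0
    index_day_fraction: float = 0.5
    start_date: dt.date = dt.date(2016, 1, 1)
    seed: int = 0
    covariate_dists: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()}
    )

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_days"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(name, f"must be a non-negative integer, got {v!r}")
        for name in ("wear_prob_case", "wear_prob_control"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(name, f"must be a probability in [0, 1], got {v!r}")
        for name in ("rate_case", "rate_control", "person_sd_wear", "person_sd_rate"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigurationError(name, f"must be >= 0, got {v!r}")
        if not (0.0 < self.index_day_fraction < 1.0):
            raise ConfigurationError(
                "index_day_fraction",
                f"must lie strictly in (0, 1), got {self.index_day_fraction!r}",
            )
        if isinstance(self.start_date, str):
            object.__setattr__(self, "start_date", dt.date.fromisoformat(self.start_date))
        elif isinstance(self.start_date, dt.datetime):
            object.__setattr__(self, "start_date", self.start_date.date())

    @property
    def index_day_offset(self) -> int:
        """Day offset of the index date within the span."""
        return int(np.floor(self.index_day_fraction * self.n_days))

    @property
    def index_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=self.index_day_offset)

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        return cls(**read_config_file(path))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d


def _shifted_prob(base_prob: float, shift: np.ndarray | float) -> np.ndarray:
    """expit(logit(p) + shift), with exact handling of p in {0, 1}."""
    if base_prob <= 0.0:
        return np.broadcast_to(0.0, np.shape(shift)) if np.ndim(shift) else 0.0
    if base_prob >= 1.0:
        return np.broadcast_to(1.0, np.shape(shift)) if np.ndim(shift) else 1.0
    return expit(logit(base_prob) + shift)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort.

    Returns
    -------
    participants : DataFrame
        Columns ``person_id, group, index_date`` plus one column per
        covariate. Cases carry the cohort index date; controls carry NaT
        (a control index is assigned later by the longitudinal module).
    steps : DataFrame
        Columns ``person_id, date, hour, steps`` -- one row per *worn*
        hour, including worn hours with zero steps. Hours absent from the
        table were not worn.

    Determinism: identical config (including seed) gives bit-identical
    output. Each person consumes an independent sub-stream spawned from
    the global seed, so enlarging the cohort does not perturb the data of
    existing persons.
    """
    n_total = config.n_cases + config.n_controls
    groups = [CASE] * config.n_cases + [CONTROL] * config.n_controls
    person_ids = [f"P{i:05d}" for i in range(n_total)]
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    index_offset = config.index_day_offset

    cov_names = list(config.covariate_dists)
    part_rows: dict[str, list] = {name: [] for name in cov_names}
    step_frames = []

    for i, (pid, group) in enumerate(zip(person_ids, groups)):
        # stable per-person sub-stream: person i's data is invariant to cohort size
        rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(i,)))
        for name in cov_names:
            dist = config.covariate_dists[name]
            cats = list(dist)
            p = np.asarray(list(dist.values()), dtype=float)
            part_rows[name].append(rng.choice(cats, p=p / p.sum()))

        u_wear = rng.normal(0.0, config.person_sd_wear) if config.person_sd_wear > 0 else 0.0
        v_rate = rng.normal(0.0, config.person_sd_rate) if config.person_sd_rate > 0 else 0.0
        base_prob = config.wear_prob_case if group == CASE else config.wear_prob_control
        drop = (
            config.post_index_wear_drop_case
            if group == CASE
            else config.post_index_wear_drop_control
        )
        # per-day log-odds shift: person offset everywhere, drop from index day on
        day_shift = np.full(config.n_days, u_wear, dtype=float)
        if drop != 0.0:
            day_shift[index_offset:] += drop
        p_day = np.asarray(_shifted_prob(base_prob, day_shift), dtype=float)

        if config.n_days == 0:
            continue
        worn = rng.random((config.n_days, 24)) < p_day[:, None]
        day_idx, hour_idx = np.nonzero(worn)
        if day_idx.size == 0:
            continue
        lam = max(0.0, (config.rate_case if group == CASE else config.rate_control) + v_rate)
        steps = rng.poisson(lam, size=day_idx.size)
        step_frames.append(
            pd.DataFrame(
                {
                    "person_id": pid,
                    "date": dates.values[day_idx],
                    "hour": hour_idx.astype(np.int64),
                    "steps": steps.astype(np.int64),
                }
            )
        )

    participants = pd.DataFrame(
        {
            "person_id": person_ids,
            "group": pd.Series(groups, dtype="object"),
            **{name: pd.Series(vals, dtype="object") for name, vals in part_rows.items()},
        }
    )
    participants["index_date"] = pd.Series(
        [pd.Timestamp(config.index_date) if g == CASE else pd.NaT for g in groups],
        dtype="datetime64[ns]",
    )

    if step_frames:
        steps_df = pd.concat(step_frames, ignore_index=True)
    else:
        steps_df = pd.DataFrame(
            {
                "person_id": pd.Series(dtype="object"),
                "date": pd.Series(dtype="datetime64[ns]"),
                "hour": pd.Series(dtype="int64"),
                "steps": pd.Series(dtype="int64"),
            }
        )
    return participants, steps_df


def _conditional_worn_mean(p: float, n_hours: int = 24) -> float:
    """E[X | X >= 1] for X ~ Binomial(n_hours, p): mean daily wear hours on worn days."""
    if p <= 0.0:
        return float("nan")
    q = (1.0 - p) ** n_hours
    return n_hours * p / (1.0 - q)


def truth_summary(config: CohortConfig) -> dict[str, float]:
    """Closed-form values of the estimands the analysis tries to recover.

    Keys
    ----
    delta_rate
        True steps-per-worn-hour difference, control − case.
    delta_wear_hours
        True mean daily wear-hour difference, control − case, at
        ``person_sd_wear = 0`` (pre-index propensities): ``24·(p_c − p_k)``.
    post_index_drop_differential_logodds
        Differential post-index log-odds shift, case − control.
    interaction_wear_hours
        Differential pre→post change in worn-day mean daily wear hours
        (case change minus control change), using the exact
        conditional-on-worn Binomial mean — the estimand of the
        longitudinal interaction model on the wear-hours outcome.
    interaction_pct_days
        Same differential on the percent-of-days-worn scale,
        ``100·(1 − (1−p)^24)`` per period and group.
    """
    pc, pk = config.wear_prob_control, config.wear_prob_case
    post_pk = float(_shifted_prob(pk, config.post_index_wear_drop_case))
    post_pc = float(_shifted_prob(pc, config.post_index_wear_drop_control))

    def pct_worn(p):
        return 100.0 * (1.0 - (1.0 - p) ** 24)

    case_change_hours = _conditional_worn_mean(post_pk) - _conditional_worn_mean(pk)
    control_change_hours = _conditional_worn_mean(post_pc) - _conditional_worn_mean(pc)
    return {
        "delta_rate": config.rate_control - config.rate_case,
        "delta_wear_hours": 24.0 * (pc - pk),
        "post_index_drop_differential_logodds": (
            config.post_index_wear_drop_case - config.post_index_wear_drop_control
        ),
        "interaction_wear_hours": case_change_hours - control_change_hours,
        "interaction_pct_days": (pct_worn(post_pk) - pct_worn(pk))
        - (pct_worn(post_pc) - pct_worn(pc)),
    }


def write_cohort(participants: pd.DataFrame, steps: pd.DataFrame, out_dir, fmt: str = "csv"):
    """Write participant and step tables to ``out_dir`` as CSV or Parquet."""
    from pathlib import Path

    from .io import write_table

    out = Path(out_dir)
    p_path = write_table(participants, out / f"participants.{fmt}")
    s_path = write_table(steps, out / f"steps.{fmt}")
    return p_path, s_path
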