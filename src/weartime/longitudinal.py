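"""Pre/post index-date wear analysis.

Each case's observation span is split at an *index date* (the diagnosis
date, floored at 2010-01-01 to predate no wearable era); controls all
share one index date — the median of the case index dates — so pre/post
contrasts are temporally aligned across groups. The question is whether
device wear declines *differentially* after diagnosis: a group × period
interaction on a wear metric, fit as a linear mixed model with a person
random intercept.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import EffectEstimate, ModelSpec, Z975, bonferroni_alpha
from .exceptions import IdentifiabilityError, WeartimeError
from .metrics import summarize_cohort

__all__ = [
    "IndexAssignment",
    "InteractionEstimate",
    "assign_case_index",
    "assign_control_index",
    "assign_cohort_indexes",
    "split_pre_post",
    "prepost_summaries",
    "fit_interaction",
]

INDEX_FLOOR = pd.Timestamp("2010-01-01")


@dataclass(frozen=True)
class IndexAssignment:
    person_id: str
    index_date: pd.Timestamp
    source: str  # diagnosis | floored_2010 | median_of_cases


def assign_case_index(
    person_id: str, diagnosis_date, floor=INDEX_FLOOR
) -> IndexAssignment:
    """Index date for a case: the diagnosis date, floored at 2010-01-01.

    Diagnoses predating consumer wearables are reset to the floor so the
    'post' period cannot begin before device data could exist.
    """
    diagnosis = pd.Timestamp(diagnosis_date)
    floor = pd.Timestamp(floor)
    if diagnosis < floor:
        return IndexAssignment(person_id, floor, "floored_2010")
    return IndexAssignment(person_id, diagnosis, "diagnosis")


def assign_control_index(case_index_dates) -> pd.Timestamp:
    """Median of the case index dates, shared by every control.

    Computed on day ordinals; an even count takes the midpoint of the two
    central dates rounded down to a whole day.
    """
    dates = [pd.Timestamp(d) for d in case_index_dates]
    if len(dates) == 0:
        raise WeartimeError("assign_control_index: no case index dates")
    ordinals = sorted(d.toordinal() for d in dates)
    n = len(ordinals)
    if n % 2 == 1:
        mid = ordinals[n // 2]
    else:
        mid = (ordinals[n // 2 - 1] + ordinals[n // 2]) // 2
    return pd.Timestamp(dt.date.fromordinal(mid))


def assign_cohort_indexes(
    participants: pd.DataFrame,
    case_label: str = "case",
    index_col: str = "index_date",
    floor=INDEX_FLOOR,
) -> pd.DataFrame:
    """Build the full index-assignment table for a cohort.

    Cases take their own (floored) index date from ``index_col``; every
    control receives the median of the case index dates. Returns columns
    ``person_id, index_date, source``.
    """
    cases = participants[participants["group"] == case_label]
    if cases[index_col].isna().any():
        missing = cases.loc[cases[index_col].isna(), "person_id"].tolist()
        raise WeartimeError(f"cases lacking an index date: {missing[:10]}")
    assignments = [
        assign_case_index(pid, d, floor)
        for pid, d in zip(cases["person_id"], cases[index_col])
    ]
    control_index = assign_control_index([a.index_date for a in assignments])
    for pid in participants.loc[participants["group"] != case_label, "person_id"]:
        assignments.append(IndexAssignment(pid, control_index, "median_of_cases"))
    return pd.DataFrame(
        {
            "person_id": [a.person_id for a in assignments],
            "index_date": [a.index_date for a in assignments],
            "source": [a.source for a in assignments],
        }
    )


def split_pre_post(person_days: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Label each person-day 'pre' (strictly before index) or 'post' (on/after).

    The index day itself belongs to the post period. Every person present
    in ``person_days`` must have an assignment.
    """
    missing = set(person_days["person_id"]) - set(assignments["person_id"])
    if missing:
        raise WeartimeError(
            f"persons without an index assignment: {sorted(missing)[:10]}"
        )
    out = person_days.merge(
        assignments[["person_id", "index_date"]], on="person_id", how="left"
    )
    out["period"] = np.where(out["date"] < out["index_date"], "pre", "post")
    return out.drop(columns=["index_date"])


def prepost_summaries(
    labeled_days: pd.DataFrame, min_days: int = 30
) -> pd.DataFrame:
    """Per-person, per-period wear summaries.

    Within each period the wear-metric conventions apply unchanged:
    ``span_days`` counts that period's calendar days in the person's span,
    ``pct_days_worn`` uses that span, and mean daily wear hours averages
    over worn days only. Eligibility (``>= min_days`` worn days) is
    re-assessed within each period.
    """
    if "period" not in labeled_days.columns:
        raise WeartimeError("prepost_summaries expects 'period'-labeled person days")
    frames = []
    for period, sub in labeled_days.groupby("period", observed=True):
        if len(sub) == 0:
            continue
        s = summarize_cohort(sub, min_days=min_days)
        # period span: count of the period's materialized days, not first-to-last
        span = sub.groupby("person_id").size().rename("span_days")
        s = s.drop(columns=["span_days"]).merge(span, on="person_id")
        s["pct_days_worn"] = 100.0 * s["days_worn"] / s["span_days"]
        s["period"] = period
        frames.append(s)
    if not frames:
        return pd.DataFrame(
            columns=[
                "person_id", "first_day", "last_day", "days_worn", "pct_days_worn",
                "mean_daily_wear_hours", "eligible", "span_days", "period",
            ]
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class InteractionEstimate:
    """Group × period interaction: the differential pre→post change."""

    outcome: str
    interaction: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected_alpha: float
    group_main: float
    period_main: float
    n_persons: int
    reference: str
    comparison: str
    excluded_persons: list

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "outcome", "interaction", "se", "ci_low", "ci_high", "p_value",
                "corrected_alpha", "group_main", "period_main", "n_persons",
                "reference", "comparison",
            )
        }
        d["significant"] = self.significant
        d["n_excluded_persons"] = len(self.excluded_persons)
        return d


def fit_interaction(
    summaries: pd.DataFrame,
    participants: pd.DataFrame,
    spec: ModelSpec | None = None,
    outcome: str = "mean_daily_wear_hours",
    require_eligible: bool = True,
) -> InteractionEstimate:
    """Fit ``outcome ~ group * period (+ covariates)`` with a person random intercept.

    The interaction coefficient is the post-minus-pre change in the
    comparison group minus the same change in the reference group (raw
    model coefficient; negative = the comparison group declines more).
    Persons lacking a usable row in either period cannot contribute a
    within-person contrast and are excluded (and reported).
    """
    import statsmodels.formula.api as smf

    spec = spec or ModelSpec(random_intercept="person_id")
    data = summaries.merge(
        participants.drop(columns=["index_date"], errors="ignore"), on="person_id", how="left"
    )
    if require_eligible and "eligible" in data.columns:
        data = data[data["eligible"]]
    data = data.dropna(subset=[outcome])
    per_person = data.groupby("person_id")["period"].nunique()
    complete = per_person[per_person == 2].index
    excluded = sorted(set(summaries["person_id"]) - set(complete))
    data = data[data["person_id"].isin(complete)]

    for col, what in ((spec.group_col, "group"), ("period", "period")):
        if data[col].nunique() < 2:
            raise IdentifiabilityError(f"{what} term has < 2 levels after filtering")
    levels = sorted(data[spec.group_col].unique())
    others = [l for l in levels if l != spec.reference]
    if spec.reference not in levels:
        raise IdentifiabilityError(f"reference level '{spec.reference}' absent")
    comparison = spec.comparison or (others[0] if len(others) == 1 else None)
    if comparison is None:
        raise IdentifiabilityError("set ModelSpec.comparison for >2 group levels")

    group_term = f"C({spec.group_col}, Treatment(reference='{spec.reference}'))"
    period_term = "C(period, Treatment(reference='pre'))"
    terms = [f"{group_term} * {period_term}"] + [f"C({c})" for c in spec.adjust]
    formula = f"{outcome} ~ " + " + ".join(terms)

    if spec.random_intercept:
        from .bias import _fit_mixedlm

        model = smf.mixedlm(formula, data, groups=data[spec.random_intercept])
        res = _fit_mixedlm(model)
        params, bse = res.fe_params, res.bse.reindex(res.fe_params.index)
    else:
        res = smf.ols(formula, data).fit()
        params, bse = res.params, res.bse

    iname = f"{group_term}[T.{comparison}]:{period_term}[T.post]"
    if iname not in params.index:
        raise IdentifiabilityError(f"interaction coefficient '{iname}' not found")
    est = float(params[iname])
    se = float(bse[iname])
    if not np.isfinite(se):
        se = 0.0
    if se > 0:
        from scipy import stats

        p = 2.0 * stats.norm.sf(abs(est / se))
    else:
        p = 0.0 if est != 0.0 else 1.0
    n_comp = spec.n_comparisons if spec.n_comparisons is not None else max(len(levels) - 1, 1)
    return InteractionEstimate(
        outcome=outcome,
        interaction=est,
        se=se,
        ci_low=est - Z975 * se,
        ci_high=est + Z975 * se,
        p_value=p,
        corrected_alpha=bonferroni_alpha(spec.alpha, n_comp),
        group_main=float(params.get(f"{group_term}[T.{comparison}]", np.nan)),
        period_main=float(params.get(f"{period_term}[T.post]", np.nan)),
        n_persons=int(data["person_id"].nunique()),
        reference=spec.reference,
        comparison=comparison,
        excluded_persons=excluded,
    )
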