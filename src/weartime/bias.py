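"""Five strategies for handling differential device wear in group comparisons.

When one group wears its device less than the other, any cumulative
activity metric (total daily steps) confounds true behaviour with device
exposure, and compliance filtering excludes the low-wear group's days
disproportionately. The strategies implemented here, each with its own
retention profile:

1. **standard** — keep only compliant days (>=10 h wear, >100 and <45,000
   steps), model total daily steps;
2. **covariate** — keep every day, add daily wear hours as a model
   covariate;
3. **normalization** — keep days with non-zero wear, model steps per worn
   hour (a rate, inherently exposure-adjusted);
4. **matching** — 1:1 nearest-neighbour matching without replacement on
   daily wear hours, so the compared groups have equivalent exposure;
5. **adaptive** — scan minimum-wear thresholds 1..10 h, testing at each
   whether wear time still differs between groups (Wilcoxon rank-sum), to
   calibrate a study-specific threshold.

Group-difference estimates are reported as *reference minus comparison*
(e.g. control − case: positive when the reference group is more active);
``fit_group_model`` itself returns the raw regression coefficient
(comparison − reference). Each estimate carries its convention.
"""

from __future__ import annotations

import bisect
import math
import warnings
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.formula.api as smf
from scipy import stats

from .compliance import ComplianceConfig, RetentionReport, apply_compliance, _report_from_mask
from .exceptions import (
    ConvergenceError,
    EmptyGroupError,
    IdentifiabilityError,
    RankDeficiencyError,
    WeartimeError,
)

__all__ = [
    "ModelSpec",
    "EffectEstimate",
    "MatchResult",
    "AdaptiveScanRow",
    "ComparisonReport",
    "bonferroni_alpha",
    "fit_group_model",
    "wilcoxon_rank_sum",
    "method_standard",
    "method_covariate",
    "method_normalization",
    "match_on_weartime",
    "method_matching",
    "adaptive_scan",
    "select_threshold",
    "compare_methods",
]

Z975 = stats.norm.ppf(0.975)


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Bonferroni-corrected significance level, ``alpha / n_comparisons``."""
    if n_comparisons < 1:
        raise WeartimeError(f"n_comparisons must be >= 1, got {n_comparisons}")
    return alpha / n_comparisons


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, group contrast, adjustment set, random intercept.

    ``n_comparisons`` sets the Bonferroni family size; when absent it
    defaults to the number of non-reference levels of the group term
    (comparing 6 groups to one reference divides alpha by 5).
    """

    outcome: str = "total_steps"
    group_col: str = "group"
    reference: str = "control"
    comparison: str | None = None
    adjust: tuple[str, ...] = ()
    extra_terms: tuple[str, ...] = ()
    random_intercept: str | None = "person_id"
    alpha: float = 0.05
    n_comparisons: int | None = None

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise WeartimeError(f"alpha must lie in (0, 1), got {self.alpha}")
        object.__setattr__(self, "adjust", tuple(self.adjust))
        object.__setattr__(self, "extra_terms", tuple(self.extra_terms))


@dataclass
class EffectEstimate:
    """A group-difference estimate with Wald 95% CI and two-sided p."""

    method: str
    outcome: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    alpha: float
    corrected_alpha: float
    n_days: int
    n_persons: int
    reference: str
    comparison: str
    sign_convention: str
    coefficients: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.corrected_alpha

    def flipped(self, method: str | None = None) -> "EffectEstimate":
        """The same estimate under the opposite sign convention."""
        convention = (
            "reference_minus_comparison"
            if self.sign_convention == "comparison_minus_reference"
            else "comparison_minus_reference"
        )
        return replace(
            self,
            method=method or self.method,
            estimate=-self.estimate,
            ci_low=-self.ci_high,
            ci_high=-self.ci_low,
            sign_convention=convention,
        )

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "method", "outcome", "estimate", "se", "ci_low", "ci_high", "p_value",
            "alpha", "corrected_alpha", "n_days", "n_persons", "reference",
            "comparison", "sign_convention",
        )}
        d["significant"] = self.significant
        return d


def _check_rank(exog: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if exog.shape[0] < exog.shape[1] or rank < exog.shape[1]:
        # pivoted QR orders independent columns first; the remainder are dependent
        _, _, piv = scipy.linalg.qr(exog, mode="economic", pivoting=True)
        raise RankDeficiencyError([names[p] for p in piv[rank:]])


def _fit_mixedlm(model):
    """REML fit with optimizer fallbacks; raises rather than degrade silently.

    A zero between-person variance (common in synthetic data without person
    heterogeneity) puts the REML optimum on the boundary, where individual
    optimizers can report failure; trying several before giving up is
    standard practice.
    """
    last = None
    for method in ("lbfgs", "bfgs", "cg", "powell"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last = exc
                continue
        if res.converged:
            return res
    raise ConvergenceError(f"mixed-effects fit did not converge ({last})")


def _build_formula(spec: ModelSpec, categorical_adjust: bool = True) -> tuple[str, str]:
    group_term = f"C({spec.group_col}, Treatment(reference='{spec.reference}'))"
    terms = [group_term]
    for cov in spec.adjust:
        terms.append(f"C({cov})" if categorical_adjust else cov)
    terms.extend(spec.extra_terms)
    return f"{spec.outcome} ~ " + " + ".join(terms), group_term


def fit_group_model(person_days: pd.DataFrame, spec: ModelSpec) -> EffectEstimate:
    """Fit the group-comparison model and return the group coefficient.

    Linear mixed-effects with a person random intercept (REML) when
    ``spec.random_intercept`` is set, ordinary least squares otherwise.
    The returned estimate is the raw regression coefficient for the
    comparison level against the reference (``comparison_minus_reference``);
    the ``method_*`` wrappers re-express it as reference − comparison.
    """
    levels = sorted(person_days[spec.group_col].dropna().unique())
    if len(levels) < 2:
        raise IdentifiabilityError(
            f"group comparison needs >= 2 levels of '{spec.group_col}', found {levels}"
        )
    if spec.reference not in levels:
        raise IdentifiabilityError(f"reference level '{spec.reference}' absent from data")
    comparison = spec.comparison
    if comparison is None:
        others = [l for l in levels if l != spec.reference]
        if len(others) > 1:
            raise IdentifiabilityError(
                f"group term has {len(levels)} levels; set ModelSpec.comparison explicitly"
            )
        comparison = others[0]

    used = [spec.outcome, spec.group_col, *spec.adjust, *spec.extra_terms]
    if spec.random_intercept:
        used.append(spec.random_intercept)
    data = person_days.dropna(subset=[c for c in used if c in person_days.columns])
    formula, group_term = _build_formula(spec)

    if spec.random_intercept:
        if data[spec.random_intercept].nunique() < 2:
            raise IdentifiabilityError("random intercept requires >= 2 grouping units")
        model = smf.mixedlm(formula, data, groups=data[spec.random_intercept])
        _check_rank(model.exog, model.exog_names)
        res = _fit_mixedlm(model)
        params = res.fe_params
        bse = res.bse.reindex(params.index)
    else:
        model = smf.ols(formula, data)
        _check_rank(model.exog, model.exog_names)
        res = model.fit()
        params, bse = res.params, res.bse

    coef_name = f"{group_term}[T.{comparison}]"
    if coef_name not in params.index:
        raise IdentifiabilityError(f"coefficient '{coef_name}' not found in fitted model")
    est = float(params[coef_name])
    se = float(bse[coef_name])
    if not np.isfinite(se):
        se = 0.0
    if se > 0:
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
    else:  # degenerate noiseless fit
        p = 0.0 if est != 0.0 else 1.0
    n_comp = spec.n_comparisons if spec.n_comparisons is not None else max(len(levels) - 1, 1)
    return EffectEstimate(
        method="model",
        outcome=spec.outcome,
        estimate=est,
        se=se,
        ci_low=est - Z975 * se,
        ci_high=est + Z975 * se,
        p_value=p,
        alpha=spec.alpha,
        corrected_alpha=bonferroni_alpha(spec.alpha, n_comp),
        n_days=int(len(data)),
        n_persons=int(data["person_id"].nunique()) if "person_id" in data else int(len(data)),
        reference=spec.reference,
        comparison=comparison,
        sign_convention="comparison_minus_reference",
        coefficients={str(k): float(v) for k, v in params.items()},
    )


def wilcoxon_rank_sum(x, y, method: str = "asymptotic") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(rank_sum_of_x, p_value)``.

    The default is the normal approximation with tie correction and
    continuity correction (mid-ranks), appropriate for the heavily tied
    integer wear-hours data of the adaptive scan. ``method="exact"``
    enumerates the null exactly and is valid for small tie-free samples.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return float("nan"), float("nan")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank sum of x
    return w, float(res.pvalue)


def _check_groups_nonempty(person_days, retained, group_col, context):
    lost = set(person_days[group_col].unique()) - set(retained[group_col].unique())
    if lost:
        raise EmptyGroupError(sorted(lost), context)


def method_standard(
    person_days: pd.DataFrame,
    compliance: ComplianceConfig | None = None,
    spec: ModelSpec | None = None,
) -> tuple[EffectEstimate, RetentionReport]:
    """Standard compliance filtering; outcome = total daily steps."""
    spec = replace(spec or ModelSpec(), outcome="total_steps")
    retained, report = apply_compliance(person_days, compliance, method="standard")
    _check_groups_nonempty(person_days, retained, spec.group_col, "compliance filtering")
    est = fit_group_model(retained, spec).flipped("standard")
    return est, report


def method_covariate(
    person_days: pd.DataFrame, spec: ModelSpec | None = None
) -> tuple[EffectEstimate, RetentionReport]:
    """Keep all days; adjust for daily wear hours as a covariate."""
    spec = spec or ModelSpec()
    spec = replace(spec, outcome="total_steps", extra_terms=(*spec.extra_terms, "wear_hours"))
    mask = pd.Series(True, index=person_days.index)
    report = _report_from_mask(person_days, mask, "covariate")
    est = fit_group_model(person_days, spec).flipped("covariate")
    return est, report


def method_normalization(
    person_days: pd.DataFrame, spec: ModelSpec | None = None
) -> tuple[EffectEstimate, RetentionReport]:
    """Keep days with non-zero wear; outcome = steps per worn hour."""
    spec = replace(spec or ModelSpec(), outcome="steps_per_hour")
    mask = person_days["wear_hours"] > 0
    report = _report_from_mask(person_days, mask, "normalization")
    retained = person_days[mask].copy()
    _check_groups_nonempty(person_days, retained, spec.group_col, "non-zero wear filtering")
    if "steps_per_hour" not in retained.columns:
        retained["steps_per_hour"] = retained["total_steps"] / retained["wear_hours"]
    est = fit_group_model(retained, spec).flipped("normalization")
    return est, report


@dataclass
class MatchResult:
    """Outcome of 1:1 nearest-neighbour wear-time matching without replacement."""

    pairs: pd.DataFrame  # case_person, case_date, control_person, control_date, distance
    unmatched_case: list[tuple]
    matched: pd.DataFrame  # the matched person-day sample (both groups)


def match_on_weartime(
    person_days: pd.DataFrame,
    group_col: str = "group",
    case_label: str = "case",
    caliper: float = math.inf,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on daily wear hours.

    Case days are processed in ascending ``(person_id, date)`` order; each
    is paired with the as-yet-unused control day minimizing the absolute
    wear-hours distance, ties broken by the control day's ascending
    ``(person_id, date)``. Controls are used at most once; case days left
    over when the control pool is exhausted (or no control lies within the
    caliper) go unmatched.
    """
    groups = set(person_days[group_col].unique())
    if case_label not in groups or len(groups) < 2:
        raise EmptyGroupError(
            [case_label] if case_label not in groups else sorted(groups), "matching"
        )

    cases = person_days[person_days[group_col] == case_label]
    controls = person_days[person_days[group_col] != case_label]
    if len(cases) == 0 or len(controls) == 0:
        raise EmptyGroupError(["case" if len(cases) == 0 else "control"], "matching")

    cases = cases.sort_values(["person_id", "date"], kind="mergesort")
    controls = controls.sort_values(["person_id", "date"], kind="mergesort")

    # bucket controls by exact wear value; each bucket is (person, date)-ordered
    buckets: dict[float, deque] = {}
    for idx, wear, pid, date in zip(
        controls.index, controls["wear_hours"], controls["person_id"], controls["date"]
    ):
        buckets.setdefault(float(wear), deque()).append((pid, date, idx))
    values = sorted(buckets)

    pair_rows = []
    unmatched: list[tuple] = []
    matched_idx: list = []
    for idx, wear, pid, date in zip(
        cases.index, cases["wear_hours"], cases["person_id"], cases["date"]
    ):
        if not values:
            unmatched.append((pid, date))
            continue
        w = float(wear)
        pos = bisect.bisect_left(values, w)
        left = values[pos - 1] if pos > 0 else None
        right = values[pos] if pos < len(values) else None
        if left is None:
            best = right
        elif right is None:
            best = left
        else:
            dl, dr = w - left, right - w
            if dl < dr:
                best = left
            elif dr < dl:
                best = right
            else:  # numeric tie: smaller (person_id, date) head wins
                best = left if buckets[left][0][:2] <= buckets[right][0][:2] else right
        dist = abs(w - best)
        if dist > caliper:
            unmatched.append((pid, date))
            continue
        c_pid, c_date, c_idx = buckets[best].popleft()
        if not buckets[best]:
            del buckets[best]
            values.remove(best)
        pair_rows.append(
            {
                "case_person": pid,
                "case_date": date,
                "control_person": c_pid,
                "control_date": c_date,
                "distance": dist,
            }
        )
        matched_idx.extend([idx, c_idx])

    pairs = pd.DataFrame(
        pair_rows, columns=["case_person", "case_date", "control_person", "control_date", "distance"]
    )
    matched = person_days.loc[matched_idx].copy()
    return MatchResult(pairs=pairs, unmatched_case=unmatched, matched=matched)


def method_matching(
    person_days: pd.DataFrame,
    spec: ModelSpec | None = None,
    case_label: str | None = None,
    caliper: float = math.inf,
) -> tuple[EffectEstimate, RetentionReport]:
    """Model total daily steps on the wear-time-matched sample."""
    spec = replace(spec or ModelSpec(), outcome="total_steps")
    label = case_label
    if label is None:
        levels = sorted(person_days[spec.group_col].unique())
        others = [l for l in levels if l != spec.reference]
        label = spec.comparison or (others[0] if len(others) == 1 else None)
        if label is None:
            raise IdentifiabilityError("cannot infer the case label; pass case_label")
    result = match_on_weartime(person_days, spec.group_col, label, caliper)
    mask = pd.Series(person_days.index.isin(result.matched.index), index=person_days.index)
    report = _report_from_mask(person_days, mask, "matching")
    est = fit_group_model(result.matched, spec).flipped("matching")
    return est, report


@dataclass
class AdaptiveScanRow:
    """One row of the adaptive-threshold scan."""

    threshold: float
    effect: EffectEstimate | None
    weartime_p: float
    retained_pct: dict[str, float]
    degenerate: bool = False


def adaptive_scan(
    person_days: pd.DataFrame,
    spec: ModelSpec | None = None,
    thresholds: Sequence[float] = tuple(range(1, 11)),
) -> list[AdaptiveScanRow]:
    """Scan minimum wear-hour thresholds, testing residual wear imbalance.

    At each threshold ``h``: retain days with ``wear_hours >= h``, fit the
    group model, and test whether wear hours still differ between groups
    (two-sided Wilcoxon rank-sum, normal approximation with tie and
    continuity corrections). A threshold that empties a group yields a
    degenerate row; the scan continues.
    """
    spec = spec or ModelSpec()
    full_counts = person_days.groupby(spec.group_col, observed=True).size()
    rows = []
    for h in thresholds:
        sub = person_days[person_days["wear_hours"] >= h]
        counts = sub.groupby(spec.group_col, observed=True).size()
        retained_pct = {
            str(g): 100.0 * counts.get(g, 0) / n for g, n in full_counts.items()
        }
        if (counts.reindex(full_counts.index).fillna(0) == 0).any():
            rows.append(
                AdaptiveScanRow(h, None, float("nan"), retained_pct, degenerate=True)
            )
            continue
        est = fit_group_model(sub, spec).flipped(f"adaptive_{h}")
        ref_wear = sub.loc[sub[spec.group_col] == est.reference, "wear_hours"]
        cmp_wear = sub.loc[sub[spec.group_col] == est.comparison, "wear_hours"]
        _, p = wilcoxon_rank_sum(cmp_wear, ref_wear)
        rows.append(AdaptiveScanRow(h, est, p, retained_pct))
    return rows


def select_threshold(rows: Sequence[AdaptiveScanRow], alpha: float = 0.05) -> float | None:
    """Smallest scanned threshold at which wear time no longer differs.

    Returns None when wear-time differences persist at every threshold —
    the calibration has no admissible cutoff in the scanned range.
    """
    if not rows:
        raise WeartimeError("select_threshold: empty scan")
    for row in sorted(rows, key=lambda r: r.threshold):
        if not row.degenerate and not math.isnan(row.weartime_p) and row.weartime_p >= alpha:
            return row.threshold
    return None


def scan_frame(rows: Sequence[AdaptiveScanRow]) -> pd.DataFrame:
    out = []
    for r in rows:
        rec = {"threshold": r.threshold, "weartime_p": r.weartime_p, "degenerate": r.degenerate}
        if r.effect is not None:
            rec.update(
                estimate=r.effect.estimate,
                ci_low=r.effect.ci_low,
                ci_high=r.effect.ci_high,
                p_value=r.effect.p_value,
            )
        for g, pct in r.retained_pct.items():
            rec[f"retained_pct_{g}"] = pct
        out.append(rec)
    return pd.DataFrame(out)


@dataclass
class ComparisonReport:
    """All five methods run on one person-day snapshot, plus the scan table."""

    effects: dict[str, EffectEstimate]
    retention: dict[str, RetentionReport]
    scan: list[AdaptiveScanRow]
    selected_threshold: float | None
    errors: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.effects.values()])

    def retention_frame(self) -> pd.DataFrame:
        frames = [r.to_frame() for r in self.retention.values()]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    def scan_frame(self) -> pd.DataFrame:
        return scan_frame(self.scan)

    def to_dict(self) -> dict:
        return {
            "effects": {k: v.to_dict() for k, v in self.effects.items()},
            "retention": {k: v.to_dict() for k, v in self.retention.items()},
            "scan": self.scan_frame().to_dict(orient="records"),
            "selected_threshold": self.selected_threshold,
            "errors": self.errors,
            "provenance": self.provenance,
        }


def compare_methods(
    person_days: pd.DataFrame,
    compliance: ComplianceConfig | None = None,
    spec: ModelSpec | None = None,
    thresholds: Sequence[float] = tuple(range(1, 11)),
) -> ComparisonReport:
    """Run all five wear-time handling methods on one input snapshot.

    Per-method failures are recorded in ``errors`` and do not abort the
    report. The adaptive method's headline estimate is taken at the
    calibrated threshold when one exists, else at the largest scanned
    threshold (the persistence case, flagged by ``selected_threshold=None``).
    """
    spec = spec or ModelSpec()
    effects: dict[str, EffectEstimate] = {}
    retention: dict[str, RetentionReport] = {}
    errors: dict[str, str] = {}

    runners = {
        "standard": lambda: method_standard(person_days, compliance, spec),
        "covariate": lambda: method_covariate(person_days, spec),
        "normalization": lambda: method_normalization(person_days, spec),
        "matching": lambda: method_matching(person_days, spec),
    }
    for name, run in runners.items():
        try:
            est, rep = run()
            effects[name], retention[name] = est, rep
        except WeartimeError as exc:
            errors[name] = str(exc)

    scan: list[AdaptiveScanRow] = []
    selected = None
    try:
        scan = adaptive_scan(person_days, spec, thresholds)
        selected = select_threshold(scan, spec.alpha)
        usable = [r for r in scan if not r.degenerate]
        if usable:
            pick = (
                next(r for r in usable if r.threshold == selected)
                if selected is not None
                else max(usable, key=lambda r: r.threshold)
            )
            effects["adaptive"] = replace(pick.effect, method="adaptive")
            mask = person_days["wear_hours"] >= pick.threshold
            retention["adaptive"] = _report_from_mask(person_days, mask, "adaptive")
        else:
            errors["adaptive"] = "all scan thresholds degenerate"
    except WeartimeError as exc:
        errors["adaptive"] = str(exc)

    return ComparisonReport(
        effects=effects,
        retention=retention,
        scan=scan,
        selected_threshold=selected,
        errors=errors,
    )
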