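"""Monte-Carlo validation harness: recovery and bias-ordering studies.

Runs the full pipeline (generate → aggregate → five methods / interaction
model) over repeated seeds on cohorts with known ground truth, and reports
whether each estimator recovers its estimand. Shared by the test suite and
the acceptance script so both measure the same computation.

The fits here are fixed-effects (OLS): the study configurations set the
person-level standard deviations to zero, so there is no person random
effect to absorb and the independence assumption holds by construction.
The mixed-effects path is exercised by the longitudinal interaction model
(two rows per person) and by unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bias import (
    ModelSpec,
    adaptive_scan,
    method_covariate,
    method_normalization,
    method_standard,
    select_threshold,
)
from .compliance import ComplianceConfig
from .longitudinal import assign_cohort_indexes, fit_interaction, prepost_summaries, split_pre_post
from .metrics import build_person_days
from .synthetic import CohortConfig, generate_cohort, truth_summary

__all__ = [
    "confounded_config",
    "equal_wear_config",
    "post_drop_config",
    "MethodStudy",
    "run_method_study",
    "run_interaction_study",
    "child_seeds",
]

#: fixed-effects model spec used throughout the studies (person SDs are 0)
STUDY_SPEC = ModelSpec(random_intercept=None)


def child_seeds(base_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds (< 2^31) from one base seed."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def confounded_config(seed: int) -> CohortConfig:
    """The confounded study condition: cases wear less *and* step less.

    100 cases / 100 controls over 180 days; per-hour wear propensity 0.45
    vs 0.75 (10.8 vs 18.0 expected daily wear hours); 40 vs 50 steps per
    worn hour; no person-level heterogeneity.
    """
    return CohortConfig(seed=seed)


def equal_wear_config(seed: int) -> CohortConfig:
    """Rate difference only: both groups wear at 0.75; rates 50 vs 40."""
    return CohortConfig(wear_prob_case=0.75, wear_prob_control=0.75, seed=seed)


def post_drop_config(seed: int) -> CohortConfig:
    """Known differential post-index wear decline (log-odds −1.0 vs −0.25)."""
    return CohortConfig(
        post_index_wear_drop_case=-1.0,
        post_index_wear_drop_control=-0.25,
        seed=seed,
    )


@dataclass
class MethodStudy:
    """Per-seed results of the five-method comparison on one config family."""

    truth: dict
    normalization_estimates: list[float]
    standard_estimates: list[float]
    covariate_estimates: list[float]
    retained_pct_case_standard: list[float]
    retained_pct_control_standard: list[float]
    scan_all_wear_p_below: list[bool]  # weartime_p < alpha at every threshold
    scan_all_effects_significant: list[bool]
    selected_thresholds: list[float | None]
    n_person_days: int = 0

    @property
    def n_seeds(self) -> int:
        return len(self.normalization_estimates)

    def mc_mean_se(self, values) -> tuple[float, float]:
        v = np.asarray(values, dtype=float)
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))

    @property
    def bias_ordering_fraction(self) -> float:
        """Fraction of seeds where |standard| exceeds |covariate| estimate."""
        s = np.abs(self.standard_estimates)
        c = np.abs(self.covariate_estimates)
        return float(np.mean(s > c))


def run_method_study(
    base_seed: int,
    n_seeds: int = 20,
    config_factory=confounded_config,
    alpha: float = 0.05,
) -> MethodStudy:
    """Generate ``n_seeds`` cohorts and run standard/covariate/normalization + scan."""
    study = MethodStudy(
        truth=truth_summary(config_factory(0)),
        normalization_estimates=[],
        standard_estimates=[],
        covariate_estimates=[],
        retained_pct_case_standard=[],
        retained_pct_control_standard=[],
        scan_all_wear_p_below=[],
        scan_all_effects_significant=[],
        selected_thresholds=[],
    )
    for seed in child_seeds(base_seed, n_seeds):
        cfg = config_factory(seed)
        participants, steps = generate_cohort(cfg)
        days = build_person_days(steps, participants)
        study.n_person_days = len(days)

        est_norm, _ = method_normalization(days, STUDY_SPEC)
        est_std, rep_std = method_standard(days, ComplianceConfig(), STUDY_SPEC)
        est_cov, _ = method_covariate(days, STUDY_SPEC)
        study.normalization_estimates.append(est_norm.estimate)
        study.standard_estimates.append(est_std.estimate)
        study.covariate_estimates.append(est_cov.estimate)
        study.retained_pct_case_standard.append(rep_std.groups["case"].retained_pct)
        study.retained_pct_control_standard.append(rep_std.groups["control"].retained_pct)

        rows = adaptive_scan(days, STUDY_SPEC)
        usable = [r for r in rows if not r.degenerate]
        study.scan_all_wear_p_below.append(
            len(usable) == len(rows) and all(r.weartime_p < alpha for r in usable)
        )
        study.scan_all_effects_significant.append(
            len(usable) == len(rows)
            and all(r.effect.p_value < r.effect.corrected_alpha for r in usable)
        )
        study.selected_thresholds.append(select_threshold(rows, alpha))
    return study


@dataclass
class InteractionStudy:
    truth: dict
    estimates: list[float]
    n_persons: int = 0

    def mc_mean_se(self) -> tuple[float, float]:
        v = np.asarray(self.estimates, dtype=float)
        return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def run_interaction_study(
    base_seed: int,
    n_seeds: int = 20,
    config_factory=post_drop_config,
    outcome: str = "mean_daily_wear_hours",
    min_days: int = 30,
) -> InteractionStudy:
    """Recover the differential post-index wear decline over repeated seeds."""
    study = InteractionStudy(truth=truth_summary(config_factory(0)), estimates=[])
    spec = replace(STUDY_SPEC, random_intercept="person_id")
    for seed in child_seeds(base_seed, n_seeds):
        cfg = config_factory(seed)
        participants, steps = generate_cohort(cfg)
        days = build_person_days(steps, participants)
        assignments = assign_cohort_indexes(participants)
        labeled = split_pre_post(days, assignments)
        summaries = prepost_summaries(labeled, min_days=min_days)
        est = fit_interaction(summaries, participants, spec, outcome=outcome)
        study.estimates.append(est.interaction)
        study.n_persons = est.n_persons
    return study
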