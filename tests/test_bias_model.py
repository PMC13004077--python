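"""Group-comparison model fitting and the five handling methods."""

import numpy as np
import pandas as pd
import pytest

from weartime import (
    ComplianceConfig,
    ModelSpec,
    bonferroni_alpha,
    compare_methods,
    fit_group_model,
    method_covariate,
    method_normalization,
    method_standard,
)
from weartime.exceptions import (
    EmptyGroupError,
    IdentifiabilityError,
    RankDeficiencyError,
    WeartimeError,
)

OLS_SPEC = ModelSpec(random_intercept=None)


def two_group_days(n_per_group, outcome_fn, rng=None, wear_fn=None):
    rows = []
    for g in ("case", "control"):
        for i in range(n_per_group):
            wear = wear_fn(g, i) if wear_fn else 12
            rows.append(
                {
                    "person_id": f"{g}{i}",
                    "date": pd.Timestamp("2020-01-01"),
                    "group": g,
                    "wear_hours": wear,
                    "total_steps": outcome_fn(g, i, wear),
                }
            )
    df = pd.DataFrame(rows)
    df["steps_per_hour"] = np.where(df["wear_hours"] > 0, df["total_steps"] / df["wear_hours"], np.nan)
    return df


def test_noiseless_group_effect_is_exact():
    days = two_group_days(6, lambda g, i, w: 100 - 10 * (g == "case"))
    est = fit_group_model(days, OLS_SPEC)
    assert est.estimate == pytest.approx(-10.0, abs=1e-9)
    assert est.se == pytest.approx(0.0, abs=1e-8)
    assert est.sign_convention == "comparison_minus_reference"


def test_ols_matches_normal_equations_oracle(rng):
    days = two_group_days(
        15,
        lambda g, i, w: float(1000 + 30 * w - 80 * (g == "case") + rng.normal(0, 50)),
        wear_fn=lambda g, i: int(rng.integers(1, 24)),
    )
    spec = ModelSpec(random_intercept=None, extra_terms=("wear_hours",))
    est = fit_group_model(days, spec)
    # independent normal-equations solve with explicit dummy coding
    X = np.column_stack(
        [
            np.ones(len(days)),
            (days["group"] == "case").astype(float),
            days["wear_hours"].astype(float),
        ]
    )
    beta = np.linalg.solve(X.T @ X, X.T @ days["total_steps"].to_numpy())
    assert est.estimate == pytest.approx(beta[1], rel=1e-9)


def test_permuted_outcome_is_null(rng):
    estimates, ses = [], []
    for _ in range(10):
        vals = rng.normal(500, 40, size=60)
        days = two_group_days(30, lambda g, i, w: 0.0)
        days["total_steps"] = rng.permutation(vals)
        est = fit_group_model(days, OLS_SPEC)
        estimates.append(est.estimate)
        ses.append(est.se)
    mean_est = np.mean(estimates)
    se_of_mean = np.mean(ses) / np.sqrt(len(estimates))
    assert abs(mean_est) < 3 * se_of_mean


def test_mixed_model_close_to_ols_on_balanced_data(rng):
    days = two_group_days(
        40, lambda g, i, w: float(500 - 50 * (g == "case") + rng.normal(0, 20))
    )
    days = pd.concat([days, days.assign(date=pd.Timestamp("2020-01-02"))], ignore_index=True)
    mixed = fit_group_model(days, ModelSpec(random_intercept="person_id"))
    ols = fit_group_model(days, OLS_SPEC)
    assert mixed.estimate == pytest.approx(ols.estimate, rel=0.05)


def test_single_group_and_collinear_errors():
    days = two_group_days(5, lambda g, i, w: 100.0)
    with pytest.raises(IdentifiabilityError):
        fit_group_model(days[days["group"] == "case"], OLS_SPEC)
    days["wear_twice"] = 2 * days["wear_hours"]
    spec = ModelSpec(random_intercept=None, extra_terms=("wear_hours", "wear_twice"))
    with pytest.raises(RankDeficiencyError):
        fit_group_model(days, spec)


def test_bonferroni():
    assert bonferroni_alpha(0.05, 5) == pytest.approx(0.01)
    assert bonferroni_alpha(0.05, 1) == 0.05
    assert bonferroni_alpha(0.05, 16) == pytest.approx(0.003125)
    with pytest.raises(WeartimeError):
        bonferroni_alpha(0.05, 0)


def test_method_standard_empties_group_errors():
    days = two_group_days(
        5, lambda g, i, w: 5000, wear_fn=lambda g, i: 5 if g == "case" else 15
    )
    with pytest.raises(EmptyGroupError, match="case"):
        method_standard(days, ComplianceConfig(), OLS_SPEC)


def test_method_covariate_retains_all_and_reports_convention():
    days = two_group_days(
        8, lambda g, i, w: float(10 * w), wear_fn=lambda g, i: (i % 12) + 1
    )
    est, report = method_covariate(days, OLS_SPEC)
    assert all(g.retained_pct == 100.0 for g in report.groups.values())
    # outcome = 10 * wear exactly, identical groups: zero group effect, wear slope 10
    assert est.estimate == pytest.approx(0.0, abs=1e-8)
    assert est.coefficients["wear_hours"] == pytest.approx(10.0, abs=1e-9)
    assert est.sign_convention == "reference_minus_comparison"


def test_method_normalization_rates_and_exclusions():
    days = two_group_days(
        4,
        lambda g, i, w: 250 * w,
        wear_fn=lambda g, i: 0 if (g == "case" and i == 0) else 4,
    )
    est, report = method_normalization(days, OLS_SPEC)
    assert report.groups["case"].retained_days == 3
    assert report.groups["case"].total_days == 4
    # every retained day is exactly 250 steps/hour in both groups
    assert est.estimate == pytest.approx(0.0, abs=1e-9)


def test_method_sign_convention_reference_minus_comparison():
    """Cases stepping less must yield a positive control-minus-case estimate."""
    days = two_group_days(
        10,
        lambda g, i, w: 400.0 - 100.0 * (g == "case"),
        wear_fn=lambda g, i: (i % 5) + 8,
    )
    est, _ = method_covariate(days, OLS_SPEC)
    assert est.estimate == pytest.approx(100.0, abs=1e-7)


def test_methods_invariant_to_row_order(small_cohort):
    _, _, _, days = small_cohort
    shuffled = days.sample(frac=1.0, random_state=3)
    for method, kwargs in [
        (method_standard, {"compliance": ComplianceConfig()}),
        (method_covariate, {}),
        (method_normalization, {}),
    ]:
        a, _ = method(days, spec=OLS_SPEC, **kwargs)
        b, _ = method(shuffled, spec=OLS_SPEC, **kwargs)
        assert a.estimate == pytest.approx(b.estimate, rel=1e-9)


def test_standard_equals_covariate_when_wear_is_orthogonal(rng):
    """All days compliant and identical wear distributions: the wear covariate
    is orthogonal to group, so both methods agree on the group effect."""
    days = two_group_days(
        200,
        lambda g, i, w: float(100 * w - 300 * (g == "case") + rng.normal(0, 10)),
        wear_fn=lambda g, i: 10 + (i % 3),  # same wear profile in both groups
    )
    est_std, _ = method_standard(days, ComplianceConfig(), OLS_SPEC)
    est_cov, _ = method_covariate(days, OLS_SPEC)
    assert est_std.estimate == pytest.approx(est_cov.estimate, rel=1e-6)


def test_compare_methods_produces_full_report(small_cohort):
    _, _, _, days = small_cohort
    report = compare_methods(days, ComplianceConfig(), OLS_SPEC)
    assert set(report.effects) == {"standard", "covariate", "normalization", "matching", "adaptive"}
    assert len(report.scan) == 10
    assert report.errors == {}
    signs = {np.sign(e.estimate) for e in report.effects.values()}
    assert signs == {1.0}  # control more active under every method
    frame = report.effects_frame()
    assert len(frame) == 5


def test_compare_methods_survives_method_failure():
    days = two_group_days(
        6,
        lambda g, i, w: 5000,
        wear_fn=lambda g, i: (4 if g == "case" else 14) + (i % 3),
    )
    days["steps_per_hour"] = days["total_steps"] / days["wear_hours"].replace(0, np.nan)
    report = compare_methods(days, ComplianceConfig(), OLS_SPEC)
    assert "standard" in report.errors  # compliance empties the case group
    assert "covariate" in report.effects
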