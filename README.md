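# weartime

Wear-time characterization and bias handling for wearable step data.

## The problem

Wearable devices (Fitbits and kin) record activity only while worn, and how
much people wear them is not random: device wear differs by demographics and
drops with depressive symptoms and clinical diagnoses. The standard practice
of analyzing only "compliant" days (≥10 hours of wear) therefore discards
days *differentially* — far more from clinical groups with low wear — and a
naive comparison of total daily steps confounds true activity with device
exposure. `weartime` implements the measurement and modelling machinery to
characterize this bias and handle it:

* **wear metrics** from intraday step counts — daily wear hours (hours with
  non-zero steps) and percentage of days worn over a person's inclusive
  first-to-last-day span, with a minimum-days eligibility rule;
* **compliance filtering with retention accounting** — per-group tallies of
  person-days kept and excluded, the quantitative face of selection bias;
* **five handling strategies** compared on the same person-day snapshot:

  | method | data used | outcome |
  |---|---|---|
  | standard | days with ≥10 h wear, 100 < steps < 45,000 | total daily steps |
  | covariate | all days; wear hours as model covariate | total daily steps |
  | normalization | days with non-zero wear | steps per worn hour |
  | matching | 1:1 nearest-neighbour on wear hours, without replacement | total daily steps |
  | adaptive | scan thresholds 1–10 h; calibrate where wear no longer differs | total daily steps |

* **pre/post index-date analysis** — does wear decline *differentially*
  after diagnosis? A group × period interaction with a person random
  intercept, with the index floored at 2010-01-01 for cases and the median
  case index date assigned to controls;
* a **synthetic cohort generator** with group-dependent per-hour wear
  propensity and steps-per-worn-hour rates, so every estimator can be
  validated against known ground truth.

Group comparisons are linear (mixed-effects with a person random intercept
when days are the grain; OLS otherwise) with Wald 95% CIs and Bonferroni
correction across the non-reference group levels. Estimates from the five
methods are reported as reference − comparison (e.g. control − case:
positive when the reference group is more active).

## Worked example

```python
from weartime import (CohortConfig, generate_cohort, build_person_days,
                      compare_methods, ComplianceConfig, ModelSpec, truth_summary)

config = CohortConfig(seed=7)           # 100 cases / 100 controls, 180 days
participants, steps = generate_cohort(config)
days = build_person_days(steps, participants)

report = compare_methods(days, ComplianceConfig(), ModelSpec(random_intercept=None))
print(report.effects_frame()[["method", "estimate", "ci_low", "ci_high", "n_days"]]
      .round(1).to_string(index=False))
print("selected adaptive threshold:", report.selected_threshold)
print("true steps/hour difference:", truth_summary(config)["delta_rate"])
rep = report.retention["standard"]
print(f"standard filter kept {rep.groups['case'].retained_pct:.1f}% of case days, "
      f"{rep.groups['control'].retained_pct:.1f}% of control days")
```

prints

```
       method  estimate  ci_low  ci_high  n_days
     standard     420.1   417.9    422.3   30571
    covariate     147.7   146.6    148.8   36000
normalization      10.0     9.9     10.0   36000
     matching     468.6   466.4    470.8   36000
     adaptive     420.1   417.9    422.3   30571
selected adaptive threshold: None
true steps/hour difference: 10.0
standard filter kept 69.8% of case days, 100.0% of control days
```

In this cohort cases truly take 10 fewer steps per worn hour *and* wear the
device 7.2 fewer hours per day. Standard compliance filtering discards 30%
of case days but almost none of the control days and reports a daily-step
gap of ~420; adding wear hours as a covariate shrinks the gap to ~148 —
much of the apparent difference was device exposure, not behaviour.
Normalization recovers the true rate difference (10 steps/hour) almost
exactly. Matching is vacuous here because the control pool is no larger
than the case pool, and the adaptive scan finds *no* threshold at which
wear time stops differing between groups (`selected_threshold: None`) —
compliance filtering alone cannot remove the confounding.

The same pipeline runs from the shell: `weartime simulate`, `weartime
metrics`, `weartime compare`, `weartime scan` and `weartime prepost`
(see `weartime --help`).

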