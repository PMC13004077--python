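# Methods

This note documents the statistical model behind `weartime`, the
conventions the implementation commits to where several were defensible,
and what the synthetic validation does and does not demonstrate.

## Wear-time measurement

Wear is inferred from steps: an hour counts as worn iff its step count is
non-zero, and a day's wear hours are the count of such hours (an integer
0–24). This is the standard step-based convention for hourly data; its
known blind spot is sedentary worn time — an hour genuinely on-wrist with
zero steps is indistinguishable from an hour off-wrist, so wear time is
underestimated in sedentary periods. The generator deliberately emits worn
hours with Poisson-zero steps as present-but-zero records to keep that
limitation visible in testing.

Per person, the **percentage of days worn** is `100 × days_worn /
span_days` where `span_days` is the *inclusive* span `(last − first) + 1`
between the first and last day with any data, and a day counts as worn
when it has at least one non-zero-step hour. The inclusive denominator is
forced by the boundary case: a person with exactly two days of data, both
worn, must read 100%. A day whose records are all zero-step counts as not
worn, consistent with the hours metric.

**Mean daily wear hours** averages over worn days only. This separates the
extensive margin (how many days the device was worn at all) from the
intensive margin (hours per worn day); averaging over all span days would
mix the two and double-count the percentage metric. With per-hour wear
propensity *p*, the worn-day mean is `E[X | X ≥ 1] = 24p / (1 − (1−p)^24)`
for `X ~ Binomial(24, p)` — the exact form `truth_summary` uses for its
estimands.

**Eligibility** requires at least `min_days = 30` days *with data* (not
span length): short records make percentage metrics unstable and
misleading.

Small covariate categories (fewer than 20 participants by default) are
pooled into an "other" label, mirroring the privacy-driven small-cell
rule common in cohort data; the pooled label itself is exempt from further
pooling so the operation is idempotent.

## Compliance filtering and retention

The day-validity rule is literal about its boundaries: retained iff
`wear_hours ≥ 10` and `100 < total_steps < 45,000`. Days with zero wear
materialized inside a person's span count in the denominator of retention
percentages, so an all-days method reads exactly 100% and the percentages
describe the full observation window rather than only recorded days.

## Group-comparison models

All group contrasts are linear models: mixed-effects with a random
intercept per person (fit by REML through statsmodels MixedLM) when the
analysis grain has repeated measures per person, OLS otherwise. Inference
is Wald throughout — normal-approximation 95% CIs and two-sided p-values,
with no small-sample degrees-of-freedom correction (Satterthwaite /
Kenward–Roger); that is the simplest defensible default and is stated here
so users with small cohorts know to tighten it. Multiplicity within one
analysis uses Bonferroni with family size equal to the number of
non-reference levels of the group term (comparing six groups against one
reference divides α by five).

Sign conventions: `fit_group_model` returns the regression coefficient as
fitted (comparison − reference); the five `method_*` wrappers re-express
the effect as reference − comparison, matching the convention "control
minus case is positive when controls are more active". Every estimate
object carries its convention explicitly.

REML with a true between-person variance of zero sits on the boundary of
the parameter space, where individual optimizers can report failure; the
fitter tries lbfgs, bfgs, cg and powell in turn and raises an explicit
convergence error rather than silently degrading.

## The five handling methods

Standard filtering and covariate adjustment model total daily steps;
normalization models steps per worn hour after dropping zero-wear days
(the rate is undefined there); matching models total daily steps on the
matched subsample. Matching is greedy 1:1 nearest-neighbour without
replacement on raw daily wear hours — for a single matching variable this
is monotone-equivalent to matching on a fitted propensity score, and raw
hours keep the distance interpretable. The greedy order is fixed
(ascending case `(person_id, date)`; ties among equidistant controls
broken by ascending control `(person_id, date)`) because determinism is a
prerequisite for testability; no caliper by default (exposed as a
parameter). The adaptive scan fits the outcome model at each threshold 1
to 10 hours and tests residual wear imbalance with a two-sided Wilcoxon
rank-sum test using the normal approximation with mid-rank tie correction
and continuity correction (the integer wear-hours data are heavily tied;
an exact-enumeration mode exists for small tie-free samples).
`select_threshold` returns the smallest threshold whose imbalance p-value
reaches α, or none when imbalance persists through 10 hours. The
comparison report presents five method rows; the adaptive row shows the
effect at the calibrated threshold when one exists, else at the largest
scanned threshold with `selected_threshold` flagged as none.

## Pre/post index-date analysis

Cases are anchored at their diagnosis date, floored at 2010-01-01 so no
"post" period predates consumer wearables; every control receives the
median of the case index dates (computed on day ordinals, even counts
rounded down to a whole day), temporally aligning the contrast. The index
day itself belongs to the post period. Period summaries re-apply the wear
conventions within each period, with the period span counted as that
period's share of the materialized person span; eligibility is re-assessed
per period and persons lacking a usable row in either period are excluded
from the interaction fit (they carry no within-person contrast) and
reported. The interaction coefficient is the post-minus-pre change in the
case group minus the same change in controls, from
`outcome ~ group * period (+ covariates)` with a person random intercept.

## The synthetic cohort

Each person-hour is worn independently with probability
`expit(logit(p_group) + u_i + drop_group·post)`, `u_i ~ N(0,
person_sd_wear)`; each worn hour's steps are `Poisson(max(0, rate_group +
v_i))`, `v_i ~ N(0, person_sd_rate)`. Hour-level Bernoulli wear (rather
than drawing a daily wear duration) is the simplest process whose marginal
matches the integer 0–24 wear-hours metric exactly. The post-index drop
applies from the cohort index day (located at `index_day_fraction` of the
span) for both groups, so the median-of-cases control index coincides with
the generative change point. Covariates are sampled from configurable
categorical distributions independent of group. Each person draws from a
deterministic sub-stream of the global seed, so enlarging a cohort never
perturbs existing persons' data.

Default condition (chosen once for the validation studies and stated here
rather than tuned): 100 cases / 100 controls over 180 days, wear
propensity 0.45 vs 0.75 (10.8 vs 18.0 expected daily wear hours), rates
40 vs 50 steps per worn hour, no person-level heterogeneity. The published
cohorts this emulates report group contrasts but not full wear or step
distributions, so these values are set for estimator-validation power, not
distributional realism. The interaction study uses post-index log-odds
drops of −1.0 (cases) vs −0.25 (controls), a differential of −4.04 worn
hours per day on the conditional-on-worn scale.

What the generator does *not* emulate: circadian activity shape (hours are
exchangeable within a day), weekday/weekend structure, autocorrelated wear
(streaks, abandonment), device metadata, and covariate–group dependence.
Passing validation therefore demonstrates estimator correctness under the
stated generative model, not robustness to those real-data features.

## Validation studies and problem sizes

The Monte-Carlo studies (`weartime.validation`) run 20 seeds of the full
pipeline at the default condition — 36,000 person-days per cohort — which
gives Monte-Carlo standard errors a couple of orders of magnitude below
the effects of interest while keeping a full run to a few minutes on one
CPU. Study fits are OLS because the generating configs set both person
SDs to zero: there is no person-level variance component to absorb, and
the independence assumption holds by construction. The mixed-effects path
is exercised by the longitudinal interaction model (two rows per person)
and by dedicated unit tests. Recovery checks require the mean estimate to
lie within three Monte-Carlo standard errors of the closed-form truth.

## Numerical and degenerate-input conventions

Wear probabilities of exactly 0 or 1 bypass the logistic shift (no ±∞
arithmetic). `steps_per_hour` is NaN on zero-wear days and such days are
excluded wherever the rate is the outcome. Empty cohorts, empty step
tables, and configs with zero persons produce empty outputs rather than
errors; operations that would be meaningless on empty input (summarizing
nobody, matching with an empty group, a single-group model) raise typed
errors naming the offending field or group. Persons with no step records
at all have an undefined span and contribute no person-days.

## Known limitations

Step-based wear detection underestimates sedentary wear (above); the
Wilcoxon p-values in the scan are asymptotic and should not be trusted for
very small groups (use the exact mode); Wald intervals are anti-
conservative for few persons; and the matching estimator inherits the
usual external-validity cost — the matched control subsample is not
representative of the control population when the wear distributions
differ strongly.
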