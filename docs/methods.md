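# Methods

## Scope and model of the trial

The package models the computational layer of a two-arm (intervention vs
usual care), 8-week mHealth feasibility trial in chronic heart failure:
instrument scoring, tailored-message logic, covariate-adaptive allocation,
device-stream metrics, and small-sample statistics, all exercised against a
synthetic cohort with known ground truth. It does not deliver messages,
talk to devices, or touch medical records; schedules and metrics are plain
CSV/JSON artifacts.

## Instrument scoring

Likert scales are scored by summing reverse-corrected item values and, for
standardized scales, mapping the sum affinely so the theoretical minimum is
0 and the maximum 100. This map is order-preserving and hits the endpoints
exactly, which the property tests assert for every shipped definition.
Clinical flags: `insufficient` when a standardized score is strictly below
the scale's cutoff (70 for the self-care and self-efficacy scales);
`mcid_change` when the absolute change from baseline reaches the scale's
minimal clinically important difference (8 points standardized; 5 for the
KCCQ-12 summary).

Missing items within a scale are prorated — the mean of answered items
stands in for each missing one — unless more than half the items are
missing, in which case the score is marked missing and left to the
downstream multiple-imputation stage. Proration is the common convention
for patient-reported outcomes; the threshold is a keyword argument.

The shipped scale definitions are editable YAML fixtures. Item counts
follow the published instrument structures (10/9/10 items for the three
self-care subscales, 10 self-efficacy items, 12-item belief scales, 15
knowledge items), but the licensed item texts are not reproduced, and the
benefit/barrier split of each 12-item belief scale is not public: the
fixtures declare 7 benefit and 5 barrier items, giving raw-sum ranges
(7–35 and 5–25) that span the magnitudes such scales report. These are
declared package defaults, not the published instruments.

## Tailoring rules

The decision algorithm is a pure predicate per rule: benefit/efficacy items
fire at answers ≤3, barrier items at ≥3 (both kinds fire at exactly 3, as
the decision table specifies), knowledge items on any incorrect option.
Missing answers skip their rule. Scheduling fills 4 slots/week on the
patient's preferred weekday/time; fired rules are consumed round-robin
across intervention targets (medication → diet → self-monitoring →
self-efficacy → knowledge) to maximize per-week target diversity, with a
rule's multi-message sequence kept consecutive and counted as N sends.
When tailored messages run out, remaining slots cycle a general-education
pool. Everything is deterministic given its inputs; each scheduled message
carries the rule id and triggering value for auditability.

## Minimization

Pocock–Simon marginal minimization with the range imbalance metric and
equal factor weights: for each candidate arm, sum over factors the
max−min across arms of the patient's-level counts after the hypothetical
assignment; choose the minimizing arm with base probability 0.7 (fair coin
on ties). Age enters as a two-level factor split at 60 years (configurable
cutoff; the cohort modeled spans 41–72). The allocation log records both
scores and the drawn uniform per patient, so sequences replay exactly under
a fixed seed. In 1,000 simulated 27-patient enrollments, minimization's
mean marginal imbalance is roughly 40% below simple 1:1 randomization's.

## Device metrics

A wear minute is a minute-level sample carrying a heart-rate value; a valid
day has ≥600 wear minutes (10 h). Weekly activity means (steps, MVPA,
sedentary, wear) use valid days only and exclude weeks with fewer than 3
valid days — the protocol's stricter ≥4-day definition also appears in the
source material, and the threshold is exposed as configuration with 3 as
the analysis default. MVPA minutes are those labeled moderate or vigorous
in the stream (for real tracker exports the mapping would be the vendor's
"fairly active" + "very active" minutes; the vendor's intensity algorithm is
out of scope). Self-monitoring adherence is the percentage of window days
with at least one measurement of the modality, after removing in-hospital
days from the denominator; duplicate same-day measurements count once. The
denominator starts at the window start (device setup day + 1 in the
generator); partial hospital days count as hospital days. BP readings are
banded by the standard guideline thresholds with the more severe of the
systolic/diastolic bands winning; the emergency flag follows the app rule
(>180 systolic or >110 diastolic). Weight alerts flag day-over-day gains
≥1.36 kg (3 lb) and separately report change since last measurement.

## Statistics

Effect sizes are Cohen's *d* on change scores with pooled SD. The standard
error is `sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2)))` and the 95% CI uses the t
quantile at n1+n2−2 df; this reproduces the published small-trial intervals
(a normal-quantile variant is available behind `ci_method="normal"`). No
Hedges small-sample correction is applied by default, matching the
published values. Group comparisons use the pooled-variance two-sample t
test; no multiple-testing adjustment is applied, as interpretation rests on
estimates and intervals rather than p values.

Multiple imputation is by chained equations with a normal linear model per
incomplete column and proper posterior draws (σ² from its scaled
inverse-χ² posterior, β from its conditional normal), predictive-mean
matching selectable; m=20 by default, fully deterministic given a seed.
Pooling follows Rubin's rules: total variance = mean within-variance +
(1+1/m)·between-variance. The imputer refuses columns >80% missing. In an
MCAR simulation (n=200, 20% missing, 50 replicates) the pooled regression
slope is recovered with bias below 1%.

Weekly trajectories use a random-intercept linear mixed model
(y ~ intercept + week, intercept | patient) fitted by REML via statsmodels,
with an optimizer fallback chain for near-degenerate variance structures.
Wald t statistics use the within-subject denominator df
N_obs − N_subjects − 1 by default (configurable); exact trial df are not
recomputable without the raw data. One-observation-per-subject input pins
the random-intercept variance to zero with a warning, in which case the fit
is exactly OLS (asserted to 1e-6 in tests). An independent closed-form REML
log-likelihood (fixed effects profiled out of the block-diagonal
V_i = σ_e²I + σ_u²J) serves as a grid oracle: the fitted optimum dominates
a 20×20 grid over the variance components on all simulated fixtures.

## Synthetic cohort generator

Defaults encode the study conditions being modeled: 11 vs 14 patients; age
truncated-normal with the location solved so the post-truncation (≥40) mean
is 56 with SD 8.3; 44% female, 92% Black, NYHA I/II/III at 24/60/16%, LVEF
categories 60/20/20%; baseline scale means/SDs near the cohort's reported
baselines; daily self-monitoring propensities beta-distributed across
patients with mean 0.864 and SD 0.1116; wear minutes ~N(1031, 421) truncated
to [0, 1440]; steps ~N(5480, 3904) truncated at 0. Visit-level questionnaire
missingness is completely at random (15% at week 4, 0 at week 8, mirroring
retention). The screening log is deterministic at the configured marginals
(504 screened, 29 enrolled, 27 randomized, 25 analyzable over 10 months).

Arm effects are injected on the change-score scale: the follow-up score is
baseline + N(d·σ_change, σ_change) in the intervention arm and
N(0, σ_change) in control, then back-solved to item responses by spreading
the rounded target sum evenly across items with stochastic remainders.
Because scores are bounded, injected effects near a scale's ceiling are
slightly attenuated in recovery, and the uncorrected d estimator carries a
small upward small-sample bias; at the default conditions the two roughly
offset and 200-replicate recovery of an injected d = 0.94 lands within 0.1
of truth. What passing recovery tests show is that the estimators are
consistent under the generator's assumptions (normal changes, MCAR
missingness, beta-Bernoulli adherence, no item-level structure); real
questionnaire data with informative missingness or item-level dependence is
outside what these tests certify.

Day-to-day adherence is independent Bernoulli given the patient propensity
(an AR(1) within-patient correlation is not modeled); hospital stays are
inserted as fixed windows, not simulated events. Minute streams are emitted
only for small fixtures via `minute_stream_for_day`, which generates a
1440-minute day consistent with a given daily summary; bulk generation
works at the per-day summary level to keep tests fast.

## Pipeline

`run_pipeline` executes simulate → score → randomize → tailor → metrics →
analyze → report under one seeded config and writes per-stage CSV/JSON plus
a manifest (config hash, seed, package version). The generator's arm labels
are the trial's allocation; the randomize stage replays minimization over
the same enrollment sequence as an audit artifact of the algorithm.
Analysis is intent-to-treat on the recorded arms, with the imputation model
conditioning on treatment group, age, gender, BMI, NYHA, LVEF, PHQ-9 and
MoCA. Reruns with the same config are byte-identical.

## Problem sizes

Simulation-based checks use: 100 replicates for mixed-model slope recovery
(11 subjects × 8 weeks), 10 fixtures for the REML grid check, 1,000
patient-streams for adherence calibration, 1,000 simulated enrollments for
the balance comparison, 50 MCAR replicates for imputation bias, and 200
replicate trials for full-pipeline effect recovery — sizes chosen so each
check's Monte-Carlo error is well inside the tolerance it asserts.
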