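# hftrialkit

Trial machinery for patient-centered mHealth heart-failure (HF) self-care
studies. The package re-implements, as a reusable and tested pipeline, the
computational layer of a small two-arm randomized trial in which patients
with chronic HF receive connected devices (scale, blood-pressure cuff,
activity tracker) plus individually tailored text messages, and are assessed
at baseline, 4 and 8 weeks:

* **instruments** — scoring of patient-reported outcomes: Likert scales
  summed and standardized to 0–100 (SCHFI v7.2 subscales, self-care
  self-efficacy; scores <70 flag insufficient self-care, MCID 8 points),
  raw-sum health-belief benefit/barrier scales, the 0–15 Dutch HF Knowledge
  Scale, and the KCCQ-12 summary (mean of four 0–100 subscales, MCID 5);
  plus eligibility screening (age ≥40, NYHA I–III, MoCA ≥22).
* **tailoring** — the message decision algorithm: a benefit or self-efficacy
  item answered ≤3 fires its message, a barrier item answered ≥3 fires, a
  wrong knowledge answer fires an education message; fired messages are
  delivered 4/week at the patient's preferred day and time, re-tailored
  after the 4-week assessment.
* **randomization** — Pocock–Simon biased-coin minimization over age group,
  sex, and NYHA class with base probability 0.7, with a full audit log.
* **device_metrics** — self-monitoring adherence (% of out-of-hospital days
  with a weight or BP measurement), wear time from heart-rate presence,
  valid days (≥600 min) and weeks (≥3 valid days), weekly step/MVPA
  summaries, ACC/AHA BP banding with an emergency flag above 180/110, and
  3-lb daily weight-gain alerts.
* **trial_stats** — change scores; Cohen's *d* on change scores with pooled
  SD, `se_d = sqrt((n1+n2)/(n1 n2) + d²/(2(n1+n2)))` and a t-quantile 95% CI;
  pooled-variance t tests; multiple imputation by chained equations (m=20)
  pooled by Rubin's rules; random-intercept linear mixed models (REML) for
  weekly trajectories; recruitment/retention arithmetic.
* **synthetic** — a synthetic-cohort generator with embedded ground truth
  (covariates, item responses with injectable arm effects, device streams
  with beta-distributed adherence propensities) so every stage is testable
  without patient data.
* **pipeline / cli** — one reproducible run: simulate → score → randomize →
  tailor → metrics → analyze → report, driven by a seeded YAML config.

## Worked example

Effect size for the 8-week change in the symptom-perception subscale, from
the two arms' change-score summaries (n, mean change, SD of change):

```python
>>> from hftrialkit.trial_stats import GroupSummary, cohen_d_from_summary
>>> intervention = GroupSummary(n=11, mean_change=7.83, sd_change=9.85)
>>> control = GroupSummary(n=14, mean_change=4.37, sd_change=10.93)
>>> r = cohen_d_from_summary(intervention, control)
>>> round(r.d, 2), (round(r.ci_low, 2), round(r.ci_high, 2))
(0.33, (-0.51, 1.17))
```

The intervention arm improved 0.33 pooled standard deviations more than
control; the interval crosses zero, as expected in a feasibility-sized
sample. A full synthetic-trial analysis in one command:

```sh
hftrialkit demo --seed 1 --out run_output
```

writes the cohort, scored visits, randomization audit, message schedule,
adherence and activity summaries, effect-size tables and mixed-model
trajectory fits into `run_output/`, and prints a results bundle, e.g.

```json
{"seed": 1, "n_per_arm": [11, 14],
 "feasibility": {"recruitment_fraction_pct": 5.8, "...": "..."},
 "mean_adherence_pct": {"weight": 84.1, "bp": 89.1}}
```

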