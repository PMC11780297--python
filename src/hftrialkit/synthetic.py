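"""Synthetic two-arm trial generator with embedded ground truth.

Generates everything the pipeline consumes — covariates, item-level
questionnaire responses at baseline/4/8 weeks, daily device records, minute
streams, and a screening log — from a :class:`TruthParams` object whose
defaults are calibrated to the study conditions this package models: a
~25-patient cohort (11 intervention vs 14 control), mean age 56 (SD 8.3,
floor 40), 44% female, NYHA I/II/III at 24/60/16%, ~86% daily self-monitoring
adherence with SD ~11% across patients, ~5480 daily steps, ~1031 daily wear
minutes.  Arm effects are injected on the change-score scale as standardized
mean differences so downstream estimates have a named truth to recover.

Item-level responses are back-solved from target scale scores: the target
raw sum is spread across items as evenly as possible, with the remainder
going to randomly chosen items.  Only scale-level behavior matters
downstream; item patterns are not modeled.

Determinism: every function takes (or derives) a numpy Generator; a fixed
seed reproduces the trial bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

from .instruments import ScaleDefinition, ValidationError, default_scale_definitions

ARMS = ("intervention", "control")


@dataclass
class TruthParams:
    """Ground-truth parameters of one synthetic trial."""

    n_per_arm: tuple[int, int] = (11, 14)
    seed: int = 0

    # covariates
    age_mean: float = 56.0
    age_sd: float = 8.3
    age_min: float = 40.0
    female_freq: float = 0.44
    black_freq: float = 0.92
    nyha_freqs: tuple[float, float, float] = (0.24, 0.60, 0.16)
    lvef_freqs: tuple[float, float, float] = (0.60, 0.20, 0.20)  # <=40, 41-49, >=50

    # baseline scale score distributions: scale_id -> (mean, sd, change_sd)
    # means/SDs on the reported scale: 0-100 for standardized scales, raw-sum
    # units for the belief scales
    scale_baselines: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "schfi_maintenance": (72.0, 16.5, 14.0),
            "schfi_symptom_perception": (77.5, 17.0, 12.0),
            "schfi_management": (70.5, 14.5, 15.0),
            "scse": (86.0, 11.0, 14.0),
            "benefits_medication": (23.8, 3.1, 3.4),
            "benefits_diet": (30.2, 3.8, 4.2),
            "benefits_selfmonitoring": (21.9, 4.4, 4.0),
            "barriers_medication": (13.1, 3.6, 2.9),
            "barriers_diet": (12.2, 3.5, 2.8),
            "barriers_selfmonitoring": (24.5, 5.5, 5.5),
        }
    )
    # injected standardized effect per (scale_id, visit)
    arm_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    # probability a patient-visit questionnaire is missing (MCAR)
    visit_missingness: dict[str, float] = field(
        default_factory=lambda: {"week4": 0.15, "week8": 0.0}
    )

    # device streams
    followup_days: int = 56
    adherence_mean: float = 0.864
    adherence_sd: float = 0.1116
    adherence_weekly_slope: float = 0.0  # additive per-week drift in propensity
    wear_minutes_mean: float = 1031.0
    wear_minutes_sd: float = 421.0
    steps_mean: float = 5480.0
    steps_sd: float = 3904.0
    mvpa_mean: float = 22.2
    mvpa_sd: float = 18.7
    weight_mean: float = 110.8
    weight_sd: float = 33.1
    systolic_mean: float = 136.6
    systolic_sd: float = 20.1
    diastolic_mean: float = 82.4
    diastolic_sd: float = 10.6

    # screening log marginals
    n_screened: int = 504
    n_eligible: int = 79
    n_enrolled: int = 29
    n_randomized: int = 27
    recruitment_months: float = 10.0

    def __post_init__(self) -> None:
        for p in (self.female_freq, self.black_freq, self.adherence_mean):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        for mean, sd, csd in self.scale_baselines.values():
            if sd <= 0 or csd <= 0:
                raise ValidationError("scale SDs must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float,
    high: float,
    size: int,
    *,
    match_mean: bool = False,
) -> np.ndarray:
    """Truncated-normal draws; with ``match_mean`` the location is shifted so
    the truncated distribution's mean equals the requested target (truncation
    otherwise biases the realized mean away from it)."""
    from scipy import stats as sps
    from scipy.optimize import brentq

    loc = mean
    if match_mean:
        def gap(mu: float) -> float:
            a, b = (low - mu) / sd, (high - mu) / sd
            return sps.truncnorm.mean(a, b, loc=mu, scale=sd) - mean

        loc = brentq(gap, low - 10 * sd, high + 10 * sd, xtol=1e-6)
    a, b = (low - loc) / sd, (high - loc) / sd
    return sps.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    v = sd**2
    if v >= mean * (1 - mean):
        raise ValidationError("beta SD too large for the requested mean")
    k = mean * (1 - mean) / v - 1
    return mean * k, (1 - mean) * k


def backsolve_items(
    target_raw_sum: int,
    definition: ScaleDefinition,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Distribute a target raw sum across a scale's items, as evenly as possible.

    The remainder after integer division goes to a random subset of items.
    Assumes homogeneous item ranges (as in the shipped fixtures).
    """
    items = definition.items
    k = len(items)
    lo, hi = items[0].response_min, items[0].response_max
    if not k * lo <= target_raw_sum <= k * hi:
        raise ValidationError("target sum outside the scale's theoretical range")
    base = target_raw_sum // k
    rem = target_raw_sum - base * k
    values = np.full(k, base, dtype=int)
    if rem:
        bump = rng.choice(k, size=rem, replace=False)
        values[bump] += 1
    return {it.item_id: int(v) for it, v in zip(items, values)}


def _score_range(definition: ScaleDefinition) -> tuple[float, float]:
    """Valid range of the reported score: 0-100 or the raw-sum span."""
    if definition.standardize:
        return 0.0, 100.0
    return definition.min_sum, definition.max_sum


def _score_to_raw(score: float, definition: ScaleDefinition) -> int:
    if not definition.standardize:
        return int(round(score))
    span = definition.max_sum - definition.min_sum
    return int(round(definition.min_sum + score / 100.0 * span))


def generate_cohort(
    truth: TruthParams,
    rng: np.random.Generator | None = None,
    definitions: dict[str, ScaleDefinition] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patients plus baseline item responses.

    Returns (patients, responses): patients with covariates and the assigned
    arm (arm sizes exactly ``truth.n_per_arm``, order shuffled), responses in
    long format (patient_id, scale_id, item_id, visit, value).
    """
    rng = rng if rng is not None else truth.rng()
    defs = definitions or default_scale_definitions()
    n = sum(truth.n_per_arm)

    ages = _truncated_normal(
        rng, truth.age_mean, truth.age_sd, truth.age_min, 95, n, match_mean=True
    )
    sex = np.where(rng.uniform(size=n) < truth.female_freq, "female", "male")
    race = np.where(rng.uniform(size=n) < truth.black_freq, "black", "white")
    nyha = rng.choice(["I", "II", "III"], size=n, p=truth.nyha_freqs)
    lvef = rng.choice(["<=40", "41-49", ">=50"], size=n, p=truth.lvef_freqs)
    moca = np.clip(np.round(rng.normal(25.9, 2.05, n)), 22, 30).astype(int)
    phq9 = np.clip(np.round(rng.normal(3.1, 3.5, n)), 0, 27).astype(int)
    bmi = _truncated_normal(rng, 36.6, 10.1, 17, 70, n)
    arms = np.array(
        [ARMS[0]] * truth.n_per_arm[0] + [ARMS[1]] * truth.n_per_arm[1], dtype=object
    )
    rng.shuffle(arms)

    patients = pd.DataFrame(
        {
            "patient_id": [f"p{i:03d}" for i in range(n)],
            "arm": arms,
            "age": np.round(ages, 1),
            "sex": sex,
            "race": race,
            "nyha": nyha,
            "lvef_category": lvef,
            "moca": moca,
            "phq9": phq9,
            "bmi": np.round(bmi, 1),
        }
    )

    rows = []
    for pid in patients["patient_id"]:
        for scale_id, (mean, sd, _csd) in truth.scale_baselines.items():
            definition = defs[scale_id]
            lo, hi = _score_range(definition)
            if not lo <= mean <= hi:
                raise ValidationError(f"infeasible target mean for {scale_id}")
            std = float(np.clip(rng.normal(mean, sd), lo, hi))
            raw = _score_to_raw(std, definition)
            for item_id, v in backsolve_items(raw, definition, rng).items():
                rows.append((pid, scale_id, item_id, "baseline", v))
    responses = pd.DataFrame(
        rows, columns=["patient_id", "scale_id", "item_id", "visit", "value"]
    )
    return patients, responses


def score_responses(
    responses: pd.DataFrame,
    definitions: dict[str, ScaleDefinition] | None = None,
) -> pd.DataFrame:
    """Long table of standardized scale scores from item responses."""
    from .instruments import ItemResponse, score_scale

    defs = definitions or default_scale_definitions()
    rows = []
    for (pid, scale_id, visit), grp in responses.groupby(
        ["patient_id", "scale_id", "visit"], sort=True
    ):
        rs = [
            ItemResponse(str(pid), str(scale_id), str(r.item_id), str(visit),
                         None if pd.isna(r.value) else int(r.value))
            for r in grp.itertuples()
        ]
        s = score_scale(rs, defs[str(scale_id)])
        rows.append((pid, scale_id, visit, s.standardized))
    return pd.DataFrame(rows, columns=["patient_id", "scale_id", "visit", "score"])


def generate_followups(
    patients: pd.DataFrame,
    baseline_scores: pd.DataFrame,
    truth: TruthParams,
    rng: np.random.Generator | None = None,
    definitions: dict[str, ScaleDefinition] | None = None,
) -> pd.DataFrame:
    """Week-4 and week-8 item responses with injected arm effects.

    The follow-up score is baseline + change, where the change is normal with
    SD = the scale's change SD and mean = injected d x change SD in the
    intervention arm (0 in control).  Whole patient-visit questionnaires go
    missing completely at random at the configured per-visit rate.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 1)
    defs = definitions or default_scale_definitions()
    arm_of = dict(zip(patients["patient_id"], patients["arm"]))
    base = baseline_scores.set_index(["patient_id", "scale_id"])["score"]

    rows = []
    for visit in ("week4", "week8"):
        miss_rate = truth.visit_missingness.get(visit, 0.0)
        for pid in patients["patient_id"]:
            missing_visit = rng.uniform() < miss_rate
            for scale_id, (_m, _sd, change_sd) in truth.scale_baselines.items():
                definition = defs[scale_id]
                if missing_visit:
                    for it in definition.items:
                        rows.append((pid, scale_id, it.item_id, visit, np.nan))
                    continue
                d = truth.arm_effects.get((scale_id, visit), 0.0)
                shift = d * change_sd if arm_of[pid] == ARMS[0] else 0.0
                delta = rng.normal(shift, change_sd)
                lo, hi = _score_range(definition)
                target = float(np.clip(base.loc[(pid, scale_id)] + delta, lo, hi))
                raw = _score_to_raw(target, definition)
                for item_id, v in backsolve_items(raw, definition, rng).items():
                    rows.append((pid, scale_id, item_id, visit, v))
    return pd.DataFrame(
        rows, columns=["patient_id", "scale_id", "item_id", "visit", "value"]
    )


def generate_device_streams(
    patients: pd.DataFrame,
    truth: TruthParams,
    rng: np.random.Generator | None = None,
    start: date = date(2019, 3, 4),
    hospital_windows: dict[str, tuple[date, date]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily device records and per-day wearable summaries for the follow-up.

    Measurement events per modality are Bernoulli with a patient-level
    propensity drawn from a beta distribution matched to the configured
    cohort mean/SD, optionally drifting linearly by week.  Wear minutes,
    steps, MVPA and sedentary minutes are drawn per day from truncated
    normals at the configured marginals.  Full 1440-row minute streams are
    intentionally not emitted here (see :func:`minute_stream_for_day`).
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 2)
    a, b = _beta_params(truth.adherence_mean, truth.adherence_sd)
    hospital_windows = hospital_windows or {}

    daily_rows = []
    activity_rows = []
    for pid in patients["patient_id"]:
        p_weight = float(rng.beta(a, b))
        p_bp = float(rng.beta(a, b))
        weight = float(rng.normal(truth.weight_mean, truth.weight_sd))
        weight = max(weight, 40.0)
        hosp = hospital_windows.get(pid)
        for day_i in range(truth.followup_days):
            d = start + timedelta(days=day_i)
            week = day_i // 7
            drift = truth.adherence_weekly_slope * week
            in_hospital = hosp is not None and hosp[0] <= d <= hosp[1]
            weight += float(rng.normal(0.0, 0.25))
            took_weight = (
                not in_hospital
                and rng.uniform() < float(np.clip(p_weight + drift, 0.0, 1.0))
            )
            took_bp = (
                not in_hospital
                and rng.uniform() < float(np.clip(p_bp + drift, 0.0, 1.0))
            )
            sys_v = int(round(rng.normal(truth.systolic_mean, truth.systolic_sd)))
            dia_v = int(round(rng.normal(truth.diastolic_mean, truth.diastolic_sd)))
            dia_v = min(dia_v, sys_v - 5)
            daily_rows.append(
                {
                    "patient_id": pid,
                    "date": d,
                    "weight_kg": round(weight, 2) if took_weight else np.nan,
                    "systolic": sys_v if took_bp else np.nan,
                    "diastolic": dia_v if took_bp else np.nan,
                    "in_hospital": in_hospital,
                }
            )
            wear = int(
                np.clip(
                    rng.normal(truth.wear_minutes_mean, truth.wear_minutes_sd), 0, 1440
                )
            )
            steps = int(max(rng.normal(truth.steps_mean, truth.steps_sd), 0))
            mvpa = int(np.clip(rng.normal(truth.mvpa_mean, truth.mvpa_sd), 0, wear))
            sedentary = int(max(wear - mvpa - rng.integers(60, 300), 0))
            activity_rows.append(
                {
                    "patient_id": pid,
                    "date": d,
                    "wear_minutes": wear,
                    "steps": steps,
                    "mvpa_minutes": mvpa,
                    "sedentary_minutes": sedentary,
                    "valid_day": wear >= 600,
                }
            )
    return pd.DataFrame(daily_rows), pd.DataFrame(activity_rows)


def minute_stream_for_day(
    patient_id: str,
    day: date,
    *,
    wear_minutes: int,
    steps: int,
    mvpa_minutes: int,
    sedentary_minutes: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """A full 1440-row minute stream consistent with one day's summary.

    Wear minutes carry a heart-rate value; steps are spread over worn,
    non-sedentary minutes; intensity labels reproduce the MVPA and sedentary
    totals.  Intended for small fixtures and oracle tests, not bulk data.
    """
    if not (0 <= wear_minutes <= 1440 and mvpa_minutes + sedentary_minutes <= wear_minutes):
        raise ValidationError("inconsistent day summary")
    minutes = np.arange(1440)
    worn = np.zeros(1440, dtype=bool)
    worn_idx = rng.choice(1440, size=wear_minutes, replace=False)
    worn[worn_idx] = True
    intensity = np.full(1440, None, dtype=object)
    shuffled = rng.permutation(worn_idx)
    mv = shuffled[:mvpa_minutes]
    sed = shuffled[mvpa_minutes : mvpa_minutes + sedentary_minutes]
    light = shuffled[mvpa_minutes + sedentary_minutes :]
    intensity[mv[: mvpa_minutes // 2]] = "moderate"
    intensity[mv[mvpa_minutes // 2 :]] = "vigorous"
    intensity[sed] = "sedentary"
    intensity[light] = "light"
    hr = np.where(worn, np.round(rng.normal(75, 12, 1440)), np.nan)
    step_col = np.zeros(1440, dtype=int)
    active = np.concatenate([mv, light]) if len(light) or len(mv) else np.array([], int)
    if steps and len(active):
        alloc = rng.multinomial(steps, np.ones(len(active)) / len(active))
        step_col[active] = alloc
    return pd.DataFrame(
        {
            "patient_id": patient_id,
            "datetime": [datetime.combine(day, time(0, 0)) + timedelta(minutes=int(m)) for m in minutes],
            "heart_rate": hr,
            "steps": step_col,
            "intensity": intensity,
        }
    )


def generate_screening_log(truth: TruthParams) -> pd.DataFrame:
    """Deterministic screening log reproducing the configured marginals."""
    n = truth.n_screened
    log = pd.DataFrame(
        {
            "candidate_id": [f"s{i:04d}" for i in range(n)],
            "eligible": [i < truth.n_eligible for i in range(n)],
            "enrolled": [i < truth.n_enrolled for i in range(n)],
            "randomized": [i < truth.n_randomized for i in range(n)],
        }
    )
    n_analyzable = sum(truth.n_per_arm)
    log["analyzable"] = [i < n_analyzable for i in range(n)]
    log["completed_week4"] = [i < round(0.85 * n_analyzable) for i in range(n)]
    log["completed_week8"] = [i < n_analyzable for i in range(n)]
    return log


@dataclass
class SyntheticTrial:
    truth: TruthParams
    patients: pd.DataFrame
    responses: pd.DataFrame  # item responses, all visits
    daily_records: pd.DataFrame
    activity_days: pd.DataFrame
    screening_log: pd.DataFrame


def generate_trial(truth: TruthParams) -> SyntheticTrial:
    """One complete synthetic trial from a single seed."""
    rng = truth.rng()
    patients, baseline = generate_cohort(truth, rng)
    baseline_scores = score_responses(baseline)
    followups = generate_followups(patients, baseline_scores, truth, rng)
    daily, activity = generate_device_streams(patients, truth, rng)
    return SyntheticTrial(
        truth=truth,
        patients=patients,
        responses=pd.concat([baseline, followups], ignore_index=True),
        daily_records=daily,
        activity_days=activity,
        screening_log=generate_screening_log(truth),
    )
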