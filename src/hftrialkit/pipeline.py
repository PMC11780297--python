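"""End-to-end pipeline: simulate -> score -> randomize -> tailor -> metrics -> analyze -> report.

Each stage writes plain CSV/JSON artifacts into the run directory so any
stage output can be inspected or re-loaded on its own, and the whole run is
reproducible: the manifest records the seed, a hash of the effective
configuration, and package versions, and a rerun with the same config is
byte-identical.

The synthetic generator stands in for enrollment and allocation, so the
cohort's recorded arm is the trial's randomized assignment; the randomize
stage replays biased-coin minimization over the same enrollment sequence as
an auditable artifact of the allocation algorithm (scores, drawn uniforms,
chosen arms).  Analysis is intent-to-treat on the recorded arms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import date, time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import device_metrics, randomization, tailoring, trial_stats
from .instruments import ItemResponse, ValidationError
from .synthetic import TruthParams, generate_trial, score_responses


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "run_output"
    arms: tuple[str, str] = ("intervention", "control")
    valid_week_min_days: int = 3
    ci_method: str = "t"
    imputation_m: int = 20
    age_cutoff: float = 60.0
    truth_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is required")
        if self.valid_week_min_days <= 0 or self.imputation_m <= 0:
            raise ValidationError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValidationError("config must declare a seed")
        return cls(**raw)

    def truth(self) -> TruthParams:
        overrides = dict(self.truth_overrides)
        if "arm_effects" in overrides:
            overrides["arm_effects"] = {
                (k.split("/")[0], k.split("/")[1]): float(v)
                for k, v in overrides["arm_effects"].items()
            }
        return TruthParams(seed=self.seed, **overrides)

    def digest(self) -> str:
        payload = json.dumps(
            {**asdict(self), "truth_overrides": repr(sorted(self.truth_overrides.items()))},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _encode_covariates(patients: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate matrix for the imputation model."""
    enc = pd.DataFrame(index=patients.index)
    enc["group"] = (patients["arm"] == "intervention").astype(float)
    enc["age"] = patients["age"].astype(float)
    enc["female"] = (patients["sex"] == "female").astype(float)
    enc["bmi"] = patients["bmi"].astype(float)
    enc["nyha_num"] = patients["nyha"].map({"I": 1, "II": 2, "III": 3}).astype(float)
    enc["lvef_num"] = (
        patients["lvef_category"].map({"<=40": 0, "41-49": 1, ">=50": 2}).astype(float)
    )
    enc["phq9"] = patients["phq9"].astype(float)
    enc["moca"] = patients["moca"].astype(float)
    enc["patient_id"] = patients["patient_id"].to_numpy()
    return enc


def impute_scored(
    scored: pd.DataFrame,
    patients: pd.DataFrame,
    m: int,
    seed: int,
) -> list[pd.DataFrame]:
    """Multiply impute missing scale scores; returns m completed long tables.

    Imputation models condition on treatment group, age, gender, BMI, NYHA,
    LVEF, depression (PHQ-9) and cognition (MoCA), with each (scale, visit)
    score as an outcome column.
    """
    wide = scored.pivot_table(
        index="patient_id", columns=["scale_id", "visit"], values="score",
        dropna=False,
    )
    wide.columns = [f"{s}__{v}" for s, v in wide.columns]
    cov = _encode_covariates(patients).set_index("patient_id")
    data = cov.join(wide).reset_index()
    predictors = ["group", "age", "female", "bmi", "nyha_num", "lvef_num", "phq9", "moca"]
    outcome_cols = [c for c in wide.columns]
    if not data[outcome_cols].isna().any().any():
        completed = [data.copy() for _ in range(m)]
    else:
        imp = trial_stats.mi_impute(
            data, predictors, outcome_cols=outcome_cols, m=m, seed=seed
        )
        completed = imp.datasets
    arm_of = dict(zip(patients["patient_id"], patients["arm"]))
    out = []
    for ds in completed:
        long = ds.melt(
            id_vars=["patient_id"],
            value_vars=outcome_cols,
            var_name="scale_visit",
            value_name="score",
        )
        long[["scale_id", "visit"]] = long["scale_visit"].str.split("__", expand=True)
        long["arm"] = long["patient_id"].map(arm_of)
        out.append(long[["patient_id", "arm", "scale_id", "visit", "score"]])
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the results bundle (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = config.truth()

    # --- simulate
    trial = generate_trial(truth)
    trial.patients.to_csv(out / "patients.csv", index=False)
    trial.responses.to_csv(out / "responses.csv", index=False)
    trial.daily_records.to_csv(out / "daily_records.csv", index=False)
    trial.activity_days.to_csv(out / "activity_days.csv", index=False)
    trial.screening_log.to_csv(out / "screening_log.csv", index=False)

    # --- score
    scored = score_responses(trial.responses)
    arm_of = dict(zip(trial.patients["patient_id"], trial.patients["arm"]))
    scored["arm"] = scored["patient_id"].map(arm_of)
    scored.to_csv(out / "scored.csv", index=False)

    # --- randomize (audit replay of the allocation algorithm)
    levels = [
        {
            "patient_id": r.patient_id,
            "age_group": randomization.age_level(r.age, config.age_cutoff),
            "sex": r.sex,
            "nyha": r.nyha,
        }
        for r in trial.patients.itertuples()
    ]
    assigned, state = randomization.assign_sequence(
        levels, seed=config.seed, arms=config.arms
    )
    pd.DataFrame(
        {"patient_id": trial.patients["patient_id"], "arm": assigned}
    ).to_csv(out / "randomization_assignments.csv", index=False)
    (out / "randomization_audit.json").write_text(json.dumps(state.log, indent=1))

    # --- tailor (intervention patients only)
    bank = tailoring.load_message_bank()
    schedule_rows = []
    baseline_items = trial.responses[trial.responses["visit"] == "baseline"]
    for pid, arm in arm_of.items():
        if arm != config.arms[0]:
            continue
        rs = [
            ItemResponse(
                str(r.patient_id), str(r.scale_id), str(r.item_id), "baseline",
                None if pd.isna(r.value) else int(r.value),
            )
            for r in baseline_items[baseline_items["patient_id"] == pid].itertuples()
        ]
        fired = tailoring.evaluate_rules(rs, bank["rules"])
        sched = tailoring.schedule_messages(
            fired,
            start=date(2019, 3, 4),
            weeks=4,
            preference=(0, time(10, 0)),
            general_pool=bank["general_pool"],
            patient_id=pid,
        )
        for at, mid, rid in sched.entries:
            schedule_rows.append(
                {"patient_id": pid, "datetime": at.isoformat(), "message_id": mid,
                 "rule_id": rid}
            )
    pd.DataFrame(schedule_rows).to_csv(out / "message_schedule.csv", index=False)

    # --- device metrics
    window = (
        trial.daily_records["date"].min(),
        trial.daily_records["date"].max(),
    )
    adherence_rows = []
    weekly_rows = []
    for pid, grp in trial.daily_records.groupby("patient_id"):
        for modality in ("weight", "bp"):
            s = device_metrics.self_monitoring_adherence(grp, modality, window)
            adherence_rows.append(
                {
                    "patient_id": pid,
                    "modality": modality,
                    "eligible_days": s.eligible_days,
                    "adherent_days": s.adherent_days,
                    "adherence_pct": s.adherence_pct,
                }
            )
            for wk, pct in enumerate(s.weekly_series, start=1):
                weekly_rows.append(
                    {"patient_id": pid, "modality": modality, "week": wk,
                     "adherence_pct": pct}
                )
    adherence = pd.DataFrame(adherence_rows)
    weekly_adherence = pd.DataFrame(weekly_rows)
    adherence.to_csv(out / "self_monitoring_adherence.csv", index=False)
    weekly_adherence.to_csv(out / "weekly_adherence.csv", index=False)

    weekly_activity = pd.concat(
        [
            device_metrics.weekly_activity_summary(
                grp, min_valid_days=config.valid_week_min_days
            ).assign(patient_id=pid)
            for pid, grp in trial.activity_days.groupby("patient_id")
        ],
        ignore_index=True,
    )
    weekly_activity.to_csv(out / "weekly_activity.csv", index=False)

    # --- analyze
    completed = impute_scored(
        scored[["patient_id", "scale_id", "visit", "score"]],
        trial.patients,
        m=config.imputation_m,
        seed=config.seed + 11,
    )
    results = trial_stats.build_results_tables(completed, arms=config.arms)
    results.to_csv(out / "results_tables.csv", index=False)

    intervention_ids = {p for p, a in arm_of.items() if a == config.arms[0]}
    lmm_results = {}
    for modality in ("weight", "bp"):
        series = weekly_adherence[
            (weekly_adherence["modality"] == modality)
            & (weekly_adherence["patient_id"].isin(intervention_ids))
        ].rename(columns={"adherence_pct": "y"})
        fit = trial_stats.fit_random_intercept_lmm(series, y_col="y", week_col="week")
        lmm_results[f"adherence_{modality}"] = fit
    steps_series = weekly_activity[
        weekly_activity["patient_id"].isin(intervention_ids)
    ].rename(columns={"steps": "y"})
    if steps_series["y"].notna().sum() >= 4:
        lmm_results["daily_steps"] = trial_stats.fit_random_intercept_lmm(
            steps_series, y_col="y", week_col="week"
        )
    lmm_table = pd.DataFrame(
        [
            {"outcome": k, **{f: getattr(v, f) for f in (
                "intercept", "intercept_se", "slope", "slope_se", "slope_t", "df",
                "slope_p", "random_intercept_var", "residual_var")}}
            for k, v in lmm_results.items()
        ]
    )
    lmm_table.to_csv(out / "lmm_trajectories.csv", index=False)

    feas = trial_stats.feasibility_metrics(
        trial.screening_log, months=truth.recruitment_months
    )

    # --- report
    bundle = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "n_per_arm": list(truth.n_per_arm),
        "feasibility": asdict(feas),
        "mean_adherence_pct": {
            m: float(adherence[adherence["modality"] == m]["adherence_pct"].mean())
            for m in ("weight", "bp")
        },
        "results_rows": len(results),
    }
    (out / "results_bundle.json").write_text(json.dumps(bundle, indent=1))

    import hftrialkit

    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "package_version": hftrialkit.__version__,
        "stages": [
            "simulate", "score", "randomize", "tailor", "metrics", "analyze",
            "report",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {
        "trial": trial,
        "scored": scored,
        "results": results,
        "lmm": lmm_results,
        "feasibility": feas,
        "adherence": adherence,
        "bundle": bundle,
        "manifest": manifest,
    }
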