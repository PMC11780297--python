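"""Adherence and activity metrics from connected-device streams.

Two stream shapes are consumed:

* daily device records — timestamped weight and blood-pressure measurements
  from the connected scale and cuff, one row per patient-day, with an
  in-hospital flag so protocol-required days spent in hospital are excluded
  from the adherence denominator;
* minute-level wearable samples — heart rate, steps and an intensity class
  per minute, from which wear time (minutes carrying a heart-rate value),
  valid days (>=600 wear minutes, i.e. 10 h), and weekly activity summaries
  over valid days are derived.  Weeks with fewer than 3 valid days are
  excluded from analysis by default (configurable; 4 is the stricter
  protocol definition).

Also here: the in-app feedback rules — ACC/AHA blood-pressure banding with an
emergency flag above 180/110, and day-over-day weight-gain alerts (default
3 lb = 1.36 kg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .instruments import ValidationError

VALID_DAY_WEAR_MINUTES = 600
WEIGHT_ALERT_KG = 1.36  # 3 lb
MVPA_INTENSITIES = ("moderate", "vigorous")

BP_CATEGORIES = ("normal", "elevated", "stage1", "stage2", "crisis")


@dataclass(frozen=True)
class DailyDeviceRecord:
    patient_id: str
    date: date
    weight_kg: float | None = None
    systolic_mmHg: int | None = None
    diastolic_mmHg: int | None = None
    heart_rate_bpm: float | None = None
    in_hospital: bool = False

    def __post_init__(self) -> None:
        if self.weight_kg is not None and self.weight_kg <= 0:
            raise ValidationError("weight must be positive")
        if (
            self.systolic_mmHg is not None
            and self.diastolic_mmHg is not None
            and self.systolic_mmHg <= self.diastolic_mmHg
        ):
            raise ValidationError("systolic must exceed diastolic")


@dataclass
class AdherenceSummary:
    patient_id: str
    window: tuple[date, date]
    eligible_days: int
    adherent_days: int
    adherence_pct: float | None
    weekly_series: list[float | None] = field(default_factory=list)


def wear_minutes(day_samples: pd.DataFrame) -> int:
    """Minutes of wear in one patient-day: samples with a heart-rate value."""
    if day_samples.empty:
        return 0
    return int(day_samples["heart_rate"].notna().sum())


def valid_day(wear_min: int) -> bool:
    """A valid wearable day has at least 10 hours (600 minutes) of wear."""
    if not 0 <= wear_min <= 1440:
        raise ValidationError("wear minutes must lie in [0, 1440]")
    return wear_min >= VALID_DAY_WEAR_MINUTES


def daily_summaries(minute_samples: pd.DataFrame) -> pd.DataFrame:
    """Collapse a minute stream to per patient-day wear/steps/MVPA/sedentary.

    Expects columns patient_id, datetime, heart_rate, steps, intensity.
    """
    df = minute_samples.copy()
    df["date"] = pd.to_datetime(df["datetime"]).dt.date
    grouped = df.groupby(["patient_id", "date"])
    out = grouped.agg(
        wear_minutes=("heart_rate", lambda s: int(s.notna().sum())),
        steps=("steps", "sum"),
        mvpa_minutes=("intensity", lambda s: int(s.isin(MVPA_INTENSITIES).sum())),
        sedentary_minutes=("intensity", lambda s: int((s == "sedentary").sum())),
    ).reset_index()
    out["valid_day"] = out["wear_minutes"] >= VALID_DAY_WEAR_MINUTES
    return out


def weekly_activity_summary(
    days: pd.DataFrame,
    *,
    min_valid_days: int = 3,
    start: date | None = None,
) -> pd.DataFrame:
    """Per-week means of daily steps, MVPA, sedentary and wear minutes.

    ``days`` is the per-day table from :func:`daily_summaries` for one
    patient.  Days are binned into consecutive 7-day windows from ``start``
    (default: the first day present).  Weeks with fewer than
    ``min_valid_days`` valid days are kept in the output but their means are
    missing; means are computed over valid days only.
    """
    if days.empty:
        return pd.DataFrame(
            columns=["week", "n_valid_days", "steps", "mvpa_minutes",
                     "sedentary_minutes", "wear_minutes"]
        )
    days = days.sort_values("date").reset_index(drop=True)
    origin = start or days["date"].iloc[0]
    week_idx = days["date"].map(lambda d: (d - origin).days // 7)
    rows = []
    for week, grp in days.groupby(week_idx):
        valid = grp[grp["valid_day"]]
        row: dict = {"week": int(week) + 1, "n_valid_days": len(valid)}
        for col in ("steps", "mvpa_minutes", "sedentary_minutes", "wear_minutes"):
            row[col] = float(valid[col].mean()) if len(valid) >= min_valid_days else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def self_monitoring_adherence(
    records: list[DailyDeviceRecord] | pd.DataFrame,
    modality: str,
    window: tuple[date, date],
) -> AdherenceSummary:
    """Percentage of protocol-required days with a measurement of one modality.

    ``modality`` is ``"weight"`` or ``"bp"``.  Days flagged in-hospital are
    removed from the denominator; duplicate same-day measurements count once.
    The weekly series (7-day windows from the window start) feeds trajectory
    models.
    """
    if modality not in ("weight", "bp"):
        raise ValidationError(f"unknown modality {modality!r}")
    if isinstance(records, pd.DataFrame):
        recs = [
            DailyDeviceRecord(
                patient_id=str(r.patient_id),
                date=r.date if isinstance(r.date, date) else pd.Timestamp(r.date).date(),
                weight_kg=None if pd.isna(r.weight_kg) else float(r.weight_kg),
                systolic_mmHg=None if pd.isna(r.systolic) else int(r.systolic),
                diastolic_mmHg=None if pd.isna(r.diastolic) else int(r.diastolic),
                in_hospital=bool(r.in_hospital),
            )
            for r in records.itertuples()
        ]
    else:
        recs = list(records)

    start, end = window
    if end < start:
        raise ValidationError("empty window")
    pid = recs[0].patient_id if recs else ""

    def measured(r: DailyDeviceRecord) -> bool:
        if modality == "weight":
            return r.weight_kg is not None
        return r.systolic_mmHg is not None and r.diastolic_mmHg is not None

    hospital_days = {r.date for r in recs if r.in_hospital}
    measured_days = {r.date for r in recs if measured(r) and start <= r.date <= end}

    n_days = (end - start).days + 1
    all_days = [start + timedelta(days=i) for i in range(n_days)]
    eligible = [d for d in all_days if d not in hospital_days]
    adherent = [d for d in eligible if d in measured_days]

    pct = 100.0 * len(adherent) / len(eligible) if eligible else None

    weekly: list[float | None] = []
    for w in range(0, n_days, 7):
        wk = all_days[w : w + 7]
        elig = [d for d in wk if d not in hospital_days]
        adh = [d for d in elig if d in measured_days]
        weekly.append(100.0 * len(adh) / len(elig) if elig else None)

    return AdherenceSummary(
        patient_id=pid,
        window=window,
        eligible_days=len(eligible),
        adherent_days=len(adherent),
        adherence_pct=pct,
        weekly_series=weekly,
    )


def classify_bp(systolic: int, diastolic: int) -> tuple[str, bool]:
    """ACC/AHA blood-pressure band plus an emergency flag.

    Bands: normal <120/<80; elevated 120-129/<80; stage 1 130-139 or 80-89;
    stage 2 140-179 or 90-119; hypertensive crisis >=180 or >=120.  When the
    two readings fall in different bands the more severe wins.  The app-level
    emergency advice triggers above 180/110 (systolic > 180 or diastolic
    > 110).
    """
    if systolic <= 0 or diastolic <= 0 or systolic <= diastolic:
        raise ValidationError("non-physiological blood pressure reading")

    def sys_band(s: int) -> int:
        if s >= 180:
            return 4
        if s >= 140:
            return 3
        if s >= 130:
            return 2
        if s >= 120:
            return 1
        return 0

    def dia_band(d: int) -> int:
        if d >= 120:
            return 4
        if d >= 90:
            return 3
        if d >= 80:
            return 2
        return 0

    category = BP_CATEGORIES[max(sys_band(systolic), dia_band(diastolic))]
    emergency = systolic > 180 or diastolic > 110
    return category, emergency


def weight_change_alert(
    series: list[tuple[date, float]],
    threshold_kg: float = WEIGHT_ALERT_KG,
) -> pd.DataFrame:
    """Flag day-over-day weight gains at or above the alert threshold.

    ``series`` must be date-ordered (date, weight_kg) pairs.  A day is
    flagged when the gain since the previous calendar day reaches the
    threshold (default 3 lb = 1.36 kg).  The change since the last
    measurement of any age is also reported, mirroring the in-app feedback.
    """
    rows = []
    prev: tuple[date, float] | None = None
    for d, w in series:
        if prev is not None and d < prev[0]:
            raise ValidationError("weight series must be date-ordered")
        change = None if prev is None else w - prev[1]
        daily_gain = (
            change
            if prev is not None and (d - prev[0]).days == 1
            else None
        )
        rows.append(
            {
                "date": d,
                "weight_kg": w,
                "change_since_last": change,
                "daily_gain": daily_gain,
                "alert": daily_gain is not None and daily_gain >= threshold_kg,
            }
        )
        prev = (d, w)
    return pd.DataFrame(rows)
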