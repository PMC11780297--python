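"""Scoring of patient-reported-outcome instruments used in heart-failure self-care trials.

The trial instruments fall into three scoring families:

* Likert scales whose item sum is rescaled to 0-100 (SCHFI v7.2 subscales,
  Self-Care Self-Efficacy).  Scores below 70 indicate insufficient self-care /
  inadequate self-efficacy; the minimal clinically important difference (MCID)
  is an 8-point change in the standardized score.
* Raw-sum Likert scales (the health-belief benefit and barrier subscales).
* Knowledge tests counted as number correct (Dutch Heart Failure Knowledge
  Scale, 0-15) and the KCCQ-12 whose summary is the mean of four 0-100
  subscale scores (MCID 5 points).

Item metadata lives in :class:`ScaleDefinition` objects, loadable from YAML,
so the engine itself is instrument-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

VISITS = ("baseline", "week4", "week8")


class ValidationError(ValueError):
    """Raised when responses or definitions violate their declared contract."""


@dataclass(frozen=True)
class ItemDefinition:
    item_id: str
    response_min: int = 1
    response_max: int = 5
    reverse_scored: bool = False

    def __post_init__(self) -> None:
        if self.response_min >= self.response_max:
            raise ValidationError(
                f"item {self.item_id}: response_min must be < response_max"
            )


@dataclass(frozen=True)
class ScaleDefinition:
    """Metadata for one instrument (sub)scale."""

    scale_id: str
    items: tuple[ItemDefinition, ...]
    standardize: bool = True
    threshold_insufficient: float | None = None
    mcid: float | None = None

    def __post_init__(self) -> None:
        if not self.items:
            raise ValidationError(f"scale {self.scale_id}: items must be non-empty")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"scale {self.scale_id}: duplicate item ids")
        if self.mcid is not None and self.mcid <= 0:
            raise ValidationError(f"scale {self.scale_id}: mcid must be > 0")

    @property
    def min_sum(self) -> float:
        return float(sum(it.response_min for it in self.items))

    @property
    def max_sum(self) -> float:
        return float(sum(it.response_max for it in self.items))

    def item(self, item_id: str) -> ItemDefinition:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise ValidationError(f"scale {self.scale_id}: unknown item {item_id!r}")


@dataclass(frozen=True)
class ItemResponse:
    """One answered (or missing) item at one visit."""

    patient_id: str
    scale_id: str
    item_id: str
    visit: str
    value: int | None

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValidationError(f"unknown visit {self.visit!r}")


@dataclass
class ScaleScore:
    patient_id: str
    scale_id: str
    visit: str
    raw_sum: float | None
    standardized: float | None
    n_missing_items: int = 0
    flags: set[str] = field(default_factory=set)

    @property
    def missing(self) -> bool:
        return self.standardized is None


def _reverse_corrected(value: int, item: ItemDefinition) -> float:
    if item.reverse_scored:
        return item.response_min + item.response_max - value
    return float(value)


def score_scale(
    responses: Sequence[ItemResponse],
    definition: ScaleDefinition,
    *,
    max_missing_fraction: float = 0.5,
) -> ScaleScore:
    """Score one patient/visit on one scale.

    Reverse-scored items are flipped, item values are summed and, when the
    definition asks for it, the sum is rescaled affinely so the theoretical
    minimum maps to 0 and the maximum to 100.  Missing items are prorated
    (the mean of answered items is imputed) unless more than
    ``max_missing_fraction`` of items are missing, in which case the score is
    marked missing.
    """
    if not responses:
        raise ValidationError("no responses supplied")
    pids = {r.patient_id for r in responses}
    visits = {r.visit for r in responses}
    if len(pids) != 1 or len(visits) != 1:
        raise ValidationError("responses must belong to one patient and one visit")
    if any(r.scale_id != definition.scale_id for r in responses):
        raise ValidationError("response scale_id does not match definition")

    seen: dict[str, int | None] = {}
    for r in responses:
        item = definition.item(r.item_id)
        if r.item_id in seen:
            raise ValidationError(f"duplicate item {r.item_id!r}")
        if r.value is not None and not (
            item.response_min <= r.value <= item.response_max
        ):
            raise ValidationError(
                f"item {r.item_id!r}: value {r.value} outside "
                f"[{item.response_min}, {item.response_max}]"
            )
        seen[r.item_id] = r.value

    corrected = []
    n_missing = 0
    for it in definition.items:
        v = seen.get(it.item_id)
        if v is None:
            n_missing += 1
        else:
            corrected.append(_reverse_corrected(v, it))

    n_items = len(definition.items)
    score = ScaleScore(
        patient_id=next(iter(pids)),
        scale_id=definition.scale_id,
        visit=next(iter(visits)),
        raw_sum=None,
        standardized=None,
        n_missing_items=n_missing,
    )
    if n_missing > max_missing_fraction * n_items or not corrected:
        return score

    # prorate: answered-item mean stands in for each missing item
    raw = sum(corrected) + n_missing * (sum(corrected) / len(corrected))
    score.raw_sum = raw
    if definition.standardize:
        score.standardized = 100.0 * (raw - definition.min_sum) / (
            definition.max_sum - definition.min_sum
        )
    else:
        score.standardized = raw
    return score


def score_dhfks(
    answers: Iterable[tuple[str, str | None]],
    key: Mapping[str, str],
    *,
    patient_id: str = "",
    visit: str = "baseline",
    scale_id: str = "dhfks",
) -> ScaleScore:
    """Count correct answers on a knowledge test (0 to ``len(key)``).

    A missing answer scores as incorrect; unknown item ids are rejected.
    """
    n_correct = 0
    n_missing = 0
    seen = set()
    for item_id, chosen in answers:
        if item_id not in key:
            raise ValidationError(f"unknown knowledge item {item_id!r}")
        if item_id in seen:
            raise ValidationError(f"duplicate knowledge item {item_id!r}")
        seen.add(item_id)
        if chosen is None:
            n_missing += 1
        elif chosen == key[item_id]:
            n_correct += 1
    return ScaleScore(
        patient_id=patient_id,
        scale_id=scale_id,
        visit=visit,
        raw_sum=float(n_correct),
        standardized=float(n_correct),
        n_missing_items=n_missing,
    )


KCCQ_SUBSCALES = (
    "physical_limitation",
    "symptom_frequency",
    "quality_of_life",
    "social_limitation",
)


def score_kccq12(
    subscale_scores: Mapping[str, float | None],
    *,
    patient_id: str = "",
    visit: str = "baseline",
    change_from_baseline: float | None = None,
    mcid: float = 5.0,
) -> ScaleScore:
    """Summary score = arithmetic mean of the four 0-100 subdomain scores.

    The summary is marked missing unless all four subscales are available.
    A change of at least ``mcid`` points (default 5) from baseline sets the
    ``mcid_change`` flag.
    """
    values = []
    for name in KCCQ_SUBSCALES:
        v = subscale_scores.get(name)
        if v is not None:
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"KCCQ subscale {name} outside [0, 100]")
            values.append(float(v))
    n_missing = len(KCCQ_SUBSCALES) - len(values)
    score = ScaleScore(
        patient_id=patient_id,
        scale_id="kccq12_summary",
        visit=visit,
        raw_sum=None,
        standardized=None,
        n_missing_items=n_missing,
    )
    if n_missing:
        return score
    summary = sum(values) / len(values)
    score.raw_sum = summary
    score.standardized = summary
    if change_from_baseline is not None and abs(change_from_baseline) >= mcid:
        score.flags.add("mcid_change")
    return score


def classify_score(
    score: ScaleScore,
    definition: ScaleDefinition,
    *,
    change_from_baseline: float | None = None,
) -> set[str]:
    """Attach clinical flags to a standardized score.

    ``insufficient`` when the score is strictly below the definition's cutoff
    (e.g. <70 on SCHFI subscales), ``mcid_change`` when the absolute change
    from baseline reaches the definition's MCID.
    """
    if score.standardized is None:
        raise ValidationError("cannot classify a missing score")
    flags: set[str] = set()
    if (
        definition.threshold_insufficient is not None
        and score.standardized < definition.threshold_insufficient
    ):
        flags.add("insufficient")
    if (
        definition.mcid is not None
        and change_from_baseline is not None
        and abs(change_from_baseline) >= definition.mcid
    ):
        flags.add("mcid_change")
    score.flags |= flags
    return flags


ELIGIBLE_NYHA = ("I", "II", "III")


def screen_eligibility(
    record: Mapping[str, object],
    *,
    min_age: int = 40,
    min_moca: int = 22,
) -> tuple[bool, list[str]]:
    """Apply the trial's screening rules to one candidate record.

    Eligible iff age >= 40, NYHA class I-III, Montreal Cognitive Assessment
    score >= 22, and no exclusion flag set.  Returns the flag and the list of
    failed criteria (empty when eligible).
    """
    reasons: list[str] = []
    for fld in ("age", "nyha", "moca"):
        if fld not in record or record[fld] is None:
            raise ValidationError(f"missing required field {fld!r}")
    if int(record["age"]) < min_age:  # type: ignore[arg-type]
        reasons.append("age")
    if str(record["nyha"]).upper() not in ELIGIBLE_NYHA:
        reasons.append("nyha")
    if int(record["moca"]) < min_moca:  # type: ignore[arg-type]
        reasons.append("cognition")
    for flag in record.get("exclusions", ()) or ():  # type: ignore[union-attr]
        reasons.append(str(flag))
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# fixture I/O


def load_scale_definitions(path: str | Path) -> dict[str, ScaleDefinition]:
    """Load scale definitions from a YAML fixture file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {sid: scale_definition_from_dict(sid, spec) for sid, spec in raw.items()}


def scale_definition_from_dict(scale_id: str, spec: Mapping) -> ScaleDefinition:
    items = tuple(
        ItemDefinition(
            item_id=str(it["item_id"]),
            response_min=int(it.get("response_min", 1)),
            response_max=int(it.get("response_max", 5)),
            reverse_scored=bool(it.get("reverse_scored", False)),
        )
        for it in spec["items"]
    )
    return ScaleDefinition(
        scale_id=scale_id,
        items=items,
        standardize=bool(spec.get("standardize", True)),
        threshold_insufficient=spec.get("threshold_insufficient"),
        mcid=spec.get("mcid"),
    )


def default_scale_definitions() -> dict[str, ScaleDefinition]:
    """The scale set shipped with the package (editable YAML fixture)."""
    return load_scale_definitions(Path(__file__).parent / "data" / "scales.yaml")
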