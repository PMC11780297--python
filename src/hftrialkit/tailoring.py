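"""Tailored text-message rule engine and weekly delivery scheduler.

The intervention assesses health beliefs, self-efficacy and disease knowledge
at baseline and again at 4 weeks, and maps the item responses onto a library
of tailored messages:

* a *benefit* or *efficacy* item fires its rule when the 1-5 Likert answer is
  <= the threshold (default 3): low perceived benefit / low confidence;
* a *barrier* item fires when the answer is >= the threshold: the barrier is
  endorsed (note both kinds fire at exactly 3);
* a *knowledge* item fires when the chosen option differs from the correct
  one, triggering an education message.

Fired messages are delivered at a fixed rate (4 per week) on the patient's
preferred weekday and time of day; the schedule is a plain output artifact
(no telecom integration).  When fired messages run out, remaining weekly
slots are filled from a configurable general-education pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .instruments import ItemResponse, ValidationError

TARGET_ORDER = ("medication", "diet", "self_monitoring", "self_efficacy", "knowledge")
LIKERT_KINDS = ("benefit", "barrier", "efficacy")


@dataclass(frozen=True)
class MessageRule:
    rule_id: str
    target: str
    item_id: str
    rule_kind: str
    message_ids: tuple[str, ...]
    threshold: int | None = 3
    correct_option: str | None = None

    def __post_init__(self) -> None:
        if self.target not in TARGET_ORDER:
            raise ValidationError(f"rule {self.rule_id}: unknown target {self.target!r}")
        if not self.message_ids:
            raise ValidationError(f"rule {self.rule_id}: message_ids must be non-empty")
        if self.rule_kind in LIKERT_KINDS:
            if self.threshold is None:
                raise ValidationError(f"rule {self.rule_id}: Likert rule needs a threshold")
        elif self.rule_kind == "knowledge":
            if self.correct_option is None:
                raise ValidationError(
                    f"rule {self.rule_id}: knowledge rule needs correct_option"
                )
        else:
            raise ValidationError(f"rule {self.rule_id}: unknown kind {self.rule_kind!r}")

    def fires(self, value: int | str) -> bool:
        """The decision predicate for one response value."""
        if self.rule_kind == "knowledge":
            return str(value) != self.correct_option
        v = int(value)
        if self.rule_kind == "barrier":
            return v >= self.threshold  # type: ignore[operator]
        return v <= self.threshold  # benefit / efficacy; type: ignore[operator]


@dataclass(frozen=True)
class TailoredMessage:
    patient_id: str
    rule_id: str
    message_id: str
    triggered_at_visit: str
    reason: int | str
    target: str


@dataclass
class MessageSchedule:
    patient_id: str
    entries: list[tuple[datetime, str, str]] = field(default_factory=list)
    rate: int = 4
    preference: tuple[int, time] = (0, time(10, 0))  # (ISO weekday-1, time of day)


def evaluate_rules(
    responses: Sequence[ItemResponse | tuple],
    rules: Sequence[MessageRule],
    *,
    knowledge_answers: Mapping[str, str] | None = None,
) -> list[TailoredMessage]:
    """Run the decision algorithm over one assessment's responses.

    ``responses`` carries the Likert answers (scale_id:item_id keys are built
    from each response's scale and item); multiple-choice knowledge answers
    are passed separately as ``knowledge_answers`` keyed the same way.
    Missing responses skip their rule; items never assessed are simply absent.
    """
    values: dict[str, tuple[int | str | None, str]] = {}
    for r in responses:
        key = f"{r.scale_id}:{r.item_id}"
        values[key] = (r.value, r.visit)
    for key, chosen in (knowledge_answers or {}).items():
        values.setdefault(key, (chosen, "baseline"))

    fired: list[TailoredMessage] = []
    for rule in rules:
        if rule.item_id not in values:
            continue
        value, visit = values[rule.item_id]
        if value is None:
            continue  # missing answer: rule skipped
        if rule.fires(value):
            pid = responses[0].patient_id if responses else ""
            for mid in rule.message_ids:
                fired.append(
                    TailoredMessage(
                        patient_id=pid,
                        rule_id=rule.rule_id,
                        message_id=mid,
                        triggered_at_visit=visit,
                        reason=value,
                        target=rule.target,
                    )
                )
    return fired


def _round_robin(triggered: Sequence[TailoredMessage]) -> list[TailoredMessage]:
    """Interleave fired messages across targets in the fixed priority order.

    Within a target, rule order follows first firing; a multi-message rule
    keeps its messages consecutive in the listed order.
    """
    by_target: dict[str, list[list[TailoredMessage]]] = {t: [] for t in TARGET_ORDER}
    current_rule: dict[str, str | None] = {t: None for t in TARGET_ORDER}
    for m in triggered:
        bucket = by_target[m.target]
        if current_rule[m.target] == m.rule_id and bucket:
            bucket[-1].append(m)
        else:
            bucket.append([m])
            current_rule[m.target] = m.rule_id
    ordered: list[TailoredMessage] = []
    queues = {t: list(by_target[t]) for t in TARGET_ORDER}
    while any(queues.values()):
        for t in TARGET_ORDER:
            if queues[t]:
                ordered.extend(queues[t].pop(0))
    return ordered


def schedule_messages(
    triggered: Sequence[TailoredMessage],
    start: date,
    weeks: int,
    *,
    preference: tuple[int, time] = (0, time(10, 0)),
    rate: int = 4,
    general_pool: Sequence[str] = (),
    patient_id: str | None = None,
) -> MessageSchedule:
    """Lay fired messages onto weekly delivery slots.

    Each 7-day window starting at ``start`` carries ``rate`` slots on the
    patient's preferred weekday/time (consecutive slots one minute apart so
    ordering is explicit).  Tailored messages are consumed in round-robin
    target order; once exhausted, remaining slots cycle through the
    general-education pool (or stay empty if no pool is configured).
    Deterministic: no randomness anywhere.
    """
    if weeks < 1:
        raise ValidationError("weeks must be >= 1")
    pid = patient_id or (triggered[0].patient_id if triggered else "")
    sched = MessageSchedule(patient_id=pid, rate=rate, preference=preference)
    queue = _round_robin(triggered)

    weekday, tod = preference
    # first preferred weekday on/after start
    first = start + timedelta(days=(weekday - start.weekday()) % 7)
    n_general = 0
    for w in range(weeks):
        day = first + timedelta(weeks=w)
        for slot in range(rate):
            at = datetime.combine(day, tod) + timedelta(minutes=slot)
            if queue:
                m = queue.pop(0)
                sched.entries.append((at, m.message_id, m.rule_id))
            elif general_pool:
                mid = general_pool[n_general % len(general_pool)]
                sched.entries.append((at, mid, "general"))
                n_general += 1
    return sched


def retailor(
    patient_id: str,
    week4_responses: Sequence[ItemResponse],
    rules: Sequence[MessageRule],
    start: date,
    *,
    weeks: int = 4,
    knowledge_answers: Mapping[str, str] | None = None,
    **schedule_kwargs,
) -> tuple[list[TailoredMessage], MessageSchedule]:
    """Re-run the decision algorithm on the 4-week assessment.

    Returns the newly fired set and the rebuilt schedule for the remaining
    weeks (5-8 by default): a barrier resolved by week 4 stops messaging,
    a newly endorsed one starts it.
    """
    fired = evaluate_rules(week4_responses, rules, knowledge_answers=knowledge_answers)
    sched = schedule_messages(
        fired, start, weeks, patient_id=patient_id, **schedule_kwargs
    )
    return fired, sched


# ---------------------------------------------------------------------------
# fixture I/O


def load_message_bank(path: str | Path | None = None) -> dict:
    """Load rules, message texts and the general pool from a YAML bank."""
    if path is None:
        path = Path(__file__).parent / "data" / "messages.yaml"
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = [
        MessageRule(
            rule_id=r["rule_id"],
            target=r["target"],
            item_id=r["item_id"],
            rule_kind=r["rule_kind"],
            message_ids=tuple(r["message_ids"]),
            threshold=r.get("threshold", 3),
            correct_option=r.get("correct_option"),
        )
        for r in raw["rules"]
    ]
    return {
        "rules": rules,
        "messages": dict(raw["messages"]),
        "general_pool": list(raw.get("general_pool", ())),
    }
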