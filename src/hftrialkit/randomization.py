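"""Pocock-Simon biased-coin minimization for two-arm 1:1 allocation.

Covariate-adaptive randomization balancing a small set of prognostic factors
(by default age group, biological sex and NYHA functional class).  For each
incoming patient the marginal imbalance that each candidate arm would create
is scored as the sum, over factors, of the range of that patient's level
counts across arms after the hypothetical assignment.  The arm minimizing the
score is chosen with a fixed base probability (0.7 in the trial this package
models); ties fall back to a fair coin.  Every decision is logged with both
scores and the drawn uniform so an allocation sequence can be audited and
replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .instruments import ValidationError

DEFAULT_FACTORS: dict[str, tuple[str, ...]] = {
    "age_group": ("<60", ">=60"),
    "sex": ("male", "female"),
    "nyha": ("I", "II", "III"),
}


def age_level(age: float, cutoff: float = 60.0) -> str:
    """Discretize age into the two minimization levels (configurable cutoff)."""
    return "<60" if age < cutoff else ">=60"


@dataclass
class AllocationState:
    """Running per-(factor, level, arm) counts plus the RNG for the coin."""

    arms: tuple[str, str] = ("intervention", "control")
    factors: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_FACTORS)
    )
    base_probability: float = 0.7
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.base_probability <= 1.0:
            raise ValidationError("base_probability must lie in (0.5, 1]")
        if len(self.arms) != 2:
            raise ValidationError("exactly two arms are supported")
        self.counts: dict[tuple[str, str, str], int] = {
            (f, lv, arm): 0
            for f, levels in self.factors.items()
            for lv in levels
            for arm in self.arms
        }
        self.rng = np.random.default_rng(self.seed)
        self.log: list[dict] = []

    def n_enrolled(self, arm: str) -> int:
        f = next(iter(self.factors))
        return sum(self.counts[(f, lv, arm)] for lv in self.factors[f])

    def _check_levels(self, patient_levels: Mapping[str, str]) -> None:
        for f, levels in self.factors.items():
            lv = patient_levels.get(f)
            if lv not in levels:
                raise ValidationError(f"unknown level {lv!r} for factor {f!r}")


def imbalance_if_assigned(
    state: AllocationState,
    patient_levels: Mapping[str, str],
    candidate_arm: str,
) -> int:
    """Pocock-Simon range imbalance after a hypothetical assignment.

    Equal factor weights: score = sum over factors of
    max - min across arms of the count at the patient's level, counting the
    patient as already assigned to ``candidate_arm``.
    """
    if candidate_arm not in state.arms:
        raise ValidationError(f"unknown arm {candidate_arm!r}")
    state._check_levels(patient_levels)
    score = 0
    for f in state.factors:
        lv = patient_levels[f]
        cnts = [
            state.counts[(f, lv, arm)] + (1 if arm == candidate_arm else 0)
            for arm in state.arms
        ]
        score += max(cnts) - min(cnts)
    return score


def minimize_assign(
    state: AllocationState,
    patient_levels: Mapping[str, str],
    patient_id: str = "",
) -> str:
    """Assign one patient by biased-coin minimization and update the state."""
    scores = {
        arm: imbalance_if_assigned(state, patient_levels, arm) for arm in state.arms
    }
    a, b = state.arms
    u = float(state.rng.uniform())
    if scores[a] == scores[b]:
        chosen = a if u < 0.5 else b
    else:
        preferred = a if scores[a] < scores[b] else b
        other = b if preferred == a else a
        chosen = preferred if u < state.base_probability else other
    for f in state.factors:
        state.counts[(f, patient_levels[f], chosen)] += 1
    state.log.append(
        {
            "patient_id": patient_id,
            "levels": dict(patient_levels),
            "scores": dict(scores),
            "uniform": u,
            "arm": chosen,
        }
    )
    return chosen


def assign_sequence(
    patients: Sequence[Mapping[str, str]],
    *,
    seed: int,
    base_probability: float = 0.7,
    factors: Mapping[str, Sequence[str]] | None = None,
    arms: tuple[str, str] = ("intervention", "control"),
) -> tuple[list[str], AllocationState]:
    """Allocate an enrollment sequence; returns arms in order plus the state."""
    state = AllocationState(
        arms=arms,
        factors=dict(factors) if factors else dict(DEFAULT_FACTORS),
        base_probability=base_probability,
        seed=seed,
    )
    assigned = [
        minimize_assign(state, p, patient_id=str(p.get("patient_id", i)))
        for i, p in enumerate(patients)
    ]
    return assigned, state


def marginal_balance(state: AllocationState) -> float:
    """Mean over factors of the summed per-level ranges (smaller = better)."""
    total = 0.0
    for f, levels in state.factors.items():
        for lv in levels:
            cnts = [state.counts[(f, lv, arm)] for arm in state.arms]
            total += max(cnts) - min(cnts)
    return total / len(state.factors)
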