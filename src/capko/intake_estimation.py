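"""Capsaicinoid intake estimation over dietary-recall records.

Joins the built food database with 24-hour-recall consumption records:
each record contributes consumed grams x content (mg/100 g) / 100 under
a chosen spiciness scenario (one level applied to all level-structured
foods, or a per-food level map). Foods missing from the database
contribute zero and are reported, never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import FoodEntry, RecallRecord

__all__ = [
    "IntakeResult",
    "estimate_intake",
    "source_contribution",
    "rank_consumers",
]


@dataclass
class IntakeResult:
    """Per subject-day intakes (mg) plus a coverage report."""

    per_subject_day: dict[tuple[str, int], float]
    uncovered_codes: set[str] = field(default_factory=set)

    @property
    def total(self) -> float:
        return sum(self.per_subject_day.values())

    def per_subject_daily_mean(self) -> dict[str, float]:
        """Mean daily intake per subject over that subject's recall days."""
        sums: dict[str, float] = {}
        days: dict[str, set[int]] = {}
        for (subject, day), mg in self.per_subject_day.items():
            sums[subject] = sums.get(subject, 0.0) + mg
            days.setdefault(subject, set()).add(day)
        return {s: sums[s] / len(days[s]) for s in sums}


def _resolve_level(entry: FoodEntry, scenario: str | Mapping[str, str]) -> str | None:
    if entry.profile.is_fixed:
        return None
    if isinstance(scenario, str):
        return scenario
    return scenario[entry.food_code]


def estimate_intake(
    records: Iterable[RecallRecord],
    db: Sequence[FoodEntry],
    scenario: str | Mapping[str, str],
) -> IntakeResult:
    """Per subject-day capsaicinoid intake (mg) under a spiciness scenario."""
    by_code = {e.food_code: e for e in db}
    per: dict[tuple[str, int], float] = {}
    uncovered: set[str] = set()
    for rec in records:
        key = (rec.subject_id, rec.day)
        per.setdefault(key, 0.0)
        entry = by_code.get(rec.food_code)
        if entry is None:
            uncovered.add(rec.food_code)
            continue
        conc = entry.profile.content(_resolve_level(entry, scenario))
        per[key] += rec.consumed_mass * conc / 100.0
    return IntakeResult(per_subject_day=per, uncovered_codes=uncovered)


def source_contribution(
    records: Iterable[RecallRecord],
    db: Sequence[FoodEntry],
    scenario: str | Mapping[str, str],
) -> tuple[dict[str, float], float]:
    """Intake broken down by food category; categories sum to the total."""
    by_code = {e.food_code: e for e in db}
    contributions: dict[str, float] = {}
    total = 0.0
    for rec in records:
        entry = by_code.get(rec.food_code)
        if entry is None:
            continue
        conc = entry.profile.content(_resolve_level(entry, scenario))
        mg = rec.consumed_mass * conc / 100.0
        contributions[entry.category.value] = (
            contributions.get(entry.category.value, 0.0) + mg
        )
        total += mg
    return contributions, total


def rank_consumers(
    per_subject_intake: Mapping[str, float], quantile: float
) -> set[str]:
    """Subjects at or above the empirical intake quantile (ties included).

    Uses the inclusive linear-interpolation quantile definition
    (numpy's default, R type 7) for cross-implementation reproducibility.
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    if not per_subject_intake:
        raise ValueError("empty intake set")
    cutoff = float(np.quantile(list(per_subject_intake.values()), quantile))
    return {s for s, v in per_subject_intake.items() if v >= cutoff}
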