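"""Capsaicinoid-content calculation from source fractions.

The central arithmetic of database construction: a food containing
``p_i`` percent of capsaicinoid source ``i`` with source concentration
``c_i`` mg/100 g contributes ``sum_i p_i * c_i / 100`` mg capsaicinoid
per 100 g of food. Evaluating that sum once per spiciness level — with
the red-pepper-powder concentration swapped for each level's mean and
all other sources held fixed — yields a food's five-level profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .datamodel import CapsaicinoidProfile, SpicinessScale

__all__ = [
    "capsaicinoid_content",
    "profile_over_levels",
    "per_serving",
    "naqs_classify",
    "validate_range",
    "RangeValidation",
    "RPP",
]

#: canonical source name for red pepper powder, the level-dependent source
RPP = "red pepper powder"


def capsaicinoid_content(
    source_fractions: Mapping[str, float],
    source_concentrations: Mapping[str, float],
) -> float:
    """mg capsaicinoid per 100 g food from source fractions (%) and
    source concentrations (mg/100 g)."""
    total = 0.0
    for source, fraction in source_fractions.items():
        if source not in source_concentrations:
            raise KeyError(f"no concentration for source {source!r}")
        total += fraction * source_concentrations[source] / 100.0
    return total


def profile_over_levels(
    source_fractions: Mapping[str, float],
    scale: SpicinessScale,
    fixed_concentrations: Optional[Mapping[str, float]] = None,
    level_source: str = RPP,
) -> CapsaicinoidProfile:
    """Five-level profile: content per level of the level-dependent source.

    ``level_source`` (red pepper powder) takes each level's mean
    concentration in turn; every other declared source keeps its fixed
    concentration from ``fixed_concentrations``.
    """
    fixed = dict(fixed_concentrations or {})
    per_level = {}
    for level in scale.levels:
        concs = dict(fixed)
        concs[level_source] = level.mean_conc
        per_level[level.name] = capsaicinoid_content(source_fractions, concs)
    return CapsaicinoidProfile(per_level=per_level)


def per_serving(conc: float, serving_mass: float) -> float:
    """mg per serving from mg/100 g and the serving mass in grams."""
    if serving_mass < 0:
        raise ValueError(f"serving mass must be non-negative, got {serving_mass}")
    return conc * serving_mass / 100.0


def naqs_classify(
    conc: float, mild_upper: float = 0.4, hot_lower: float = 1.2
) -> str:
    """NAQS spiciness class of a napa cabbage kimchi content (mg/100 g).

    Certification thresholds: mild below 0.4, hot above 1.2, moderately
    hot on the closed interval in between.
    """
    if conc < 0:
        raise ValueError(f"content must be non-negative, got {conc}")
    if conc < mild_upper:
        return "mild"
    if conc > hot_lower:
        return "hot"
    return "moderately hot"


@dataclass
class RangeValidation:
    """Comparison of an estimate (or profile) against a published range."""

    passed: bool
    interval: tuple[float, float]
    inside: dict[str, float]
    outside: dict[str, float]

    @property
    def margin(self) -> float:
        """Smallest distance from any estimate to the interval (0 if inside)."""
        lo, hi = self.interval
        dists = [
            max(lo - v, v - hi, 0.0)
            for v in list(self.inside.values()) + list(self.outside.values())
        ]
        return min(dists)


def validate_range(
    estimate: float | CapsaicinoidProfile, reported: tuple[float, float]
) -> RangeValidation:
    """Check whether an estimate falls within a published measurement range.

    For a multi-level profile the check passes if any level's content
    lies inside the interval; the result reports which levels do.
    """
    lo, hi = reported
    if not lo <= hi:
        raise ValueError(f"malformed interval ({lo}, {hi})")
    if isinstance(estimate, CapsaicinoidProfile):
        values = dict(estimate.per_level)
    else:
        values = {"estimate": float(estimate)}
    inside = {k: v for k, v in values.items() if lo <= v <= hi}
    outside = {k: v for k, v in values.items() if k not in inside}
    return RangeValidation(
        passed=bool(inside), interval=(lo, hi), inside=inside, outside=outside
    )
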