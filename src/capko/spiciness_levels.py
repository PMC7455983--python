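"""Five-level spiciness scaling of red pepper powder.

Published capsaicinoid contents of red pepper powder span an order of
magnitude. After trimming exceptionally low and high values, the
retained collection is binned into five spiciness groups (mild,
slightly hot, medium hot, very hot, extremely hot) whose per-group mean
concentrations become the representative red-pepper-powder levels used
throughout database construction.

The group boundaries are configuration, not re-derived: no
boundary-selection algorithm is published, so the printed ranges are
taken as given. A concentration falling in the gap between two
consecutive ranges is assigned to the level with the nearest range
endpoint (ties to the lower, i.e. milder, level) — the rule that keeps
market samples at 70.9 and 106.7 mg/100 g in the groups they are known
to belong to.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .datamodel import LiteratureValue, SpicinessLevel, SpicinessScale

__all__ = [
    "TrimResult",
    "LevelAssignment",
    "trim_extremes",
    "assign_levels",
    "level_means",
    "classify_powder",
]


def _value(v: LiteratureValue | float) -> float:
    return v.value if isinstance(v, LiteratureValue) else float(v)


@dataclass
class TrimResult:
    """Outcome of extreme-value trimming, order preserved."""

    retained: list
    n_removed_low: int
    n_removed_high: int

    @property
    def n_removed(self) -> int:
        return self.n_removed_low + self.n_removed_high


@dataclass
class LevelAssignment:
    """Partition of literature values over the spiciness levels."""

    groups: dict[str, list]
    unclassifiable: list = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(vals) for name, vals in self.groups.items()}


def trim_extremes(
    values: Sequence[LiteratureValue | float], low_cut: float, high_cut: float
) -> TrimResult:
    """Drop values below ``low_cut`` or above ``high_cut``.

    Both cuts are exclusive removal thresholds: a value is retained iff
    ``low_cut <= v <= high_cut``. Raises if nothing survives.
    """
    if not values:
        raise ValueError("no values to trim")
    if not low_cut < high_cut:
        raise ValueError(f"low_cut {low_cut} must be below high_cut {high_cut}")
    retained, n_low, n_high = [], 0, 0
    for v in values:
        x = _value(v)
        if x < low_cut:
            n_low += 1
        elif x > high_cut:
            n_high += 1
        else:
            retained.append(v)
    if not retained:
        raise ValueError("trimming removed every value")
    return TrimResult(retained, n_low, n_high)


def _locate(x: float, scale: SpicinessScale) -> str | None:
    """Level name for concentration ``x``, or None if off-scale."""
    levels = scale.levels
    if x < levels[0].lower or x > levels[-1].upper:
        return None
    for lv in levels:
        if lv.lower <= x <= lv.upper:
            return lv.name
    # in a gap between two consecutive ranges: nearest endpoint wins,
    # ties go to the milder level
    for lo, hi in zip(levels, levels[1:]):
        if lo.upper < x < hi.lower:
            return lo.name if (x - lo.upper) <= (hi.lower - x) else hi.name
    return None  # pragma: no cover - gaps and ranges are exhaustive


def assign_levels(
    values: Sequence[LiteratureValue | float], scale: SpicinessScale
) -> LevelAssignment:
    """Partition values over the scale's levels.

    Every input lands in exactly one group or in ``unclassifiable``
    (below the first lower bound / above the last upper bound), so group
    counts plus unclassifiable count equal the input count.
    """
    groups: dict[str, list] = {name: [] for name in scale.names}
    out = LevelAssignment(groups=groups)
    for v in values:
        name = _locate(_value(v), scale)
        if name is None:
            out.unclassifiable.append(v)
        else:
            groups[name].append(v)
    return out


def level_means(
    groups: Mapping[str, Sequence[LiteratureValue | float]],
    scale: SpicinessScale | None = None,
) -> SpicinessScale:
    """Per-group arithmetic means as a scale with ``mean_conc`` populated.

    With ``scale`` given, its level boundaries are kept and the means
    replace ``mean_conc`` (every scale level must have a non-empty
    group); without it, each group's own min/max become the bounds.
    """
    means = {}
    for name, vals in groups.items():
        if not vals:
            raise ValueError(f"group {name!r} is empty")
        means[name] = statistics.fmean(_value(v) for v in vals)
    if scale is not None:
        return SpicinessScale(
            levels=[
                SpicinessLevel(
                    name=lv.name, lower=lv.lower, upper=lv.upper,
                    mean_conc=means[lv.name],
                )
                for lv in scale.levels
            ]
        )
    return SpicinessScale(
        levels=[
            SpicinessLevel(
                name=name,
                lower=min(_value(v) for v in vals),
                upper=max(_value(v) for v in vals),
                mean_conc=means[name],
            )
            for name, vals in groups.items()
        ]
    )


def classify_powder(conc: float, scale: SpicinessScale) -> str:
    """Spiciness level of a red pepper powder concentration (mg/100 g)."""
    if conc <= 0:
        raise ValueError(f"concentration must be positive, got {conc}")
    name = _locate(conc, scale)
    if name is None:
        raise ValueError(
            f"{conc} mg/100 g is outside the scale span "
            f"[{scale.levels[0].lower}, {scale.levels[-1].upper}]"
        )
    return name
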