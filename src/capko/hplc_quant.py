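"""HPLC standard-curve quantification of seasoning capsaicinoids.

Calibration standards at known concentrations give a peak-area vs.
concentration line (unweighted ordinary least squares, free intercept).
A sample's extract concentration is read off the inverted line; the
content on a per-100-g basis follows from the extract volume and the
extracted sample mass:

    mg/100 g = (area - intercept)/slope [ug/ml] * V [ml] / m [g] / 10

(the factor 10 converts ug/g to mg/100 g). Spike-recovery rates and
triplicate mean +/- SD summaries provide the assay QC; per-flavor
category means summarize the instant-noodle survey.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence

from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .datamodel import SeasoningAssay, StandardCurve

__all__ = [
    "CalibrationSeries",
    "CalibrationPoint",
    "QuantResult",
    "CategorySummary",
    "fit_standard_curve",
    "quantify_sample",
    "recovery_rate",
    "replicate_summary",
    "category_means",
]


class CalibrationPoint(BaseModel):
    concentration: float = Field(gt=0)  # ug/ml
    peak_area: float                    # arbitrary units


class CalibrationSeries(BaseModel):
    """Standard dilution series for one analyte."""

    analyte: str = "capsaicin"
    points: list[CalibrationPoint]

    @model_validator(mode="after")
    def _check(self) -> "CalibrationSeries":
        if len({p.concentration for p in self.points}) < 2:
            raise ValueError("need at least two distinct concentrations")
        return self


def fit_standard_curve(series: CalibrationSeries) -> StandardCurve:
    """Unweighted OLS line area = slope * concentration + intercept."""
    x = [p.concentration for p in series.points]
    y = [p.peak_area for p in series.points]
    fit = stats.linregress(x, y)
    return StandardCurve(
        slope=fit.slope, intercept=fit.intercept, r_squared=fit.rvalue**2
    )


@dataclass
class QuantResult:
    """Quantified content with a below-calibration-range flag."""

    mg_per_100g: float
    extract_conc: float  # ug/ml
    below_range: bool


def quantify_sample(
    peak_area: float,
    curve: StandardCurve,
    extract_volume: float = 25.0,
    sample_mass: float = 3.0,
) -> QuantResult:
    """Content (mg/100 g) of a sample from its peak area.

    An area below the fitted intercept is flagged ``below_range`` and
    clamped to zero rather than reported negative.
    """
    if sample_mass <= 0:
        raise ValueError(f"sample mass must be positive, got {sample_mass}")
    if extract_volume <= 0:
        raise ValueError(f"extract volume must be positive, got {extract_volume}")
    conc = (peak_area - curve.intercept) / curve.slope
    below = conc < 0
    conc = max(conc, 0.0)
    # ug/ml * ml / g = ug/g; /10 -> mg/100 g
    mg = conc * extract_volume / sample_mass * (100.0 / 1000.0)
    return QuantResult(mg_per_100g=mg, extract_conc=conc, below_range=below)


def recovery_rate(measured_spiked: float, baseline: float, spike: float) -> float:
    """Percent of a spiked analyte amount recovered by the assay."""
    if spike <= 0:
        raise ValueError(f"spike must be positive, got {spike}")
    return 100.0 * (measured_spiked - baseline) / spike


def replicate_summary(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator) of replicate measurements."""
    if len(values) < 2:
        raise ValueError("need at least two replicates")
    return statistics.fmean(values), statistics.stdev(values)


@dataclass
class CategorySummary:
    """Unweighted means over the assays of one (noodle type, flavor) cell."""

    n: int
    capsaicin: float
    dihydrocapsaicin: float
    total: float
    per_packet: float


def category_means(
    assays: Iterable[SeasoningAssay],
) -> dict[tuple[str, str], CategorySummary]:
    """Per (noodle type, flavor) means of the assay components.

    Note the published cup-noodle summary row equals the cup hot-flavor
    mean (the single mild cup product stands alone), so the flavor-level
    means here are the summary statistics of record.
    """
    groups: dict[tuple[str, str], list[SeasoningAssay]] = {}
    for a in assays:
        groups.setdefault((a.noodle_type, a.flavor), []).append(a)
    out = {}
    for key, rows in groups.items():
        out[key] = CategorySummary(
            n=len(rows),
            capsaicin=statistics.fmean(r.capsaicin for r in rows),
            dihydrocapsaicin=statistics.fmean(r.dihydrocapsaicin for r in rows),
            total=statistics.fmean(r.total for r in rows),
            per_packet=statistics.fmean(r.per_packet for r in rows),
        )
    return out
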