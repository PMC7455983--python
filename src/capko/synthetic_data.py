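"""Seeded generators for every input class the pipeline consumes.

The generators emulate the study's input material — literature
capsaicinoid-value collections, standardized recipes and product labels
with known true source fractions, calibration peak areas with additive
noise, and 24-hour dietary-recall records — so every stage is testable
end to end without external data. All generators are pure functions of
(seed or Generator, parameters): the same seed reproduces the same
artifact bit for bit.

Literature values are drawn uniformly over the requested span (no
distributional form is published for them); recall portion sizes are
gamma-distributed, the usual right-skewed shape of consumption amounts.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datamodel import (
    FoodEntry,
    Ingredient,
    LabelRecord,
    LiteratureValue,
    RecallRecord,
    Recipe,
    StandardCurve,
)

__all__ = [
    "gen_literature_values",
    "gen_recipe",
    "gen_labels",
    "gen_peak_areas",
    "gen_recall",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_literature_values(
    n: int,
    seed: int | np.random.Generator,
    value_range: tuple[float, float] = (10.54, 203.8),
    outlier_counts: tuple[int, int] = (3, 3),
    trim_cuts: tuple[float, float] = (10.0, 220.0),
) -> list[LiteratureValue]:
    """Literature collection: ``n`` values, of which ``outlier_counts``
    fall below/above the trim cuts and the rest lie uniformly in
    ``value_range``. Returned sorted ascending, as published collections
    are presented."""
    n_low, n_high = outlier_counts
    if n <= n_low + n_high:
        raise ValueError(f"n={n} must exceed outlier counts {outlier_counts}")
    lo, hi = value_range
    low_cut, high_cut = trim_cuts
    if not (low_cut <= lo < hi <= high_cut):
        raise ValueError("value range must lie within the trim cuts")
    rng = _rng(seed)
    body = rng.uniform(lo, hi, size=n - n_low - n_high)
    lows = rng.uniform(low_cut / 10.0, low_cut * (1 - 1e-6), size=n_low)
    highs = rng.uniform(high_cut * (1 + 1e-6), high_cut * 1.5, size=n_high)
    values = np.sort(np.concatenate([lows, body, highs]))
    return [
        LiteratureValue(value=float(v), study_id=f"synthetic-{i}")
        for i, v in enumerate(values)
    ]


def gen_recipe(
    seed: int | np.random.Generator,
    true_fraction: float,
    n_other_ingredients: int = 5,
    total_weight: float = 120.0,
) -> Recipe:
    """Recipe whose source fraction is exactly ``true_fraction`` percent.

    Other-ingredient weights are random but scaled so the full-precision
    source fraction recovers ``true_fraction`` before any rounding.
    """
    if not 0 <= true_fraction < 100:
        raise ValueError(f"true fraction must be in [0, 100), got {true_fraction}")
    rng = _rng(seed)
    source_weight = total_weight * true_fraction / 100.0
    rest = total_weight - source_weight
    shares = rng.dirichlet(np.ones(n_other_ingredients)) * rest
    ingredients = [
        Ingredient(name=f"ingredient {i}", fresh_weight=float(w))
        for i, w in enumerate(shares)
    ]
    if source_weight > 0:
        ingredients.append(
            Ingredient(name="red pepper powder", fresh_weight=source_weight)
        )
    else:  # keep the source present so the fraction is well defined
        ingredients.append(
            Ingredient(name="red pepper powder", fresh_weight=1e-12)
        )
    return Recipe(
        name=f"synthetic-{true_fraction}",
        food="synthetic kimchi",
        ingredients=ingredients,
        source_ingredient="red pepper powder",
    )


def gen_labels(
    seed: int | np.random.Generator,
    n_products: int,
    true_mean: float,
    spread: float = 0.0,
    source: str = "red pepper powder",
) -> list[LabelRecord]:
    """Product labels whose declared fractions average ``true_mean``.

    ``spread`` is the SD of a centered Gaussian perturbation; the sample
    is re-centered so the mean equals ``true_mean`` exactly.
    """
    if n_products < 1:
        raise ValueError("need at least one product")
    rng = _rng(seed)
    noise = rng.normal(0.0, spread, size=n_products) if spread > 0 else np.zeros(n_products)
    noise -= noise.mean()
    fractions = np.clip(true_mean + noise, 0.0, 100.0)
    return [
        LabelRecord(product_id=f"synthetic #{i + 1}", fractions={source: float(f)})
        for i, f in enumerate(fractions)
    ]


def gen_peak_areas(
    curve: StandardCurve,
    true_concs: Sequence[float],
    noise_sd_rel: float,
    seed: int | np.random.Generator,
) -> list[float]:
    """Peak areas on the calibration line plus relative Gaussian noise."""
    if noise_sd_rel < 0:
        raise ValueError("noise SD must be non-negative")
    rng = _rng(seed)
    areas = []
    for c in true_concs:
        area = curve.slope * c + curve.intercept
        if noise_sd_rel > 0:
            area += rng.normal(0.0, noise_sd_rel * abs(area))
        areas.append(float(area))
    return areas


def gen_recall(
    n_subjects: int,
    n_days: int,
    seed: int | np.random.Generator,
    db: Sequence[FoodEntry],
    portion_shape: float = 2.0,
    portion_scale: float = 50.0,
    foods_per_day: int = 3,
) -> list[RecallRecord]:
    """24-hour recall records over a food database.

    Each subject-day consumes ``foods_per_day`` foods sampled uniformly
    from the database with gamma(shape, scale)-distributed portions in
    grams; every generated food code resolves against ``db``.
    """
    if n_subjects < 0 or n_days < 0:
        raise ValueError("counts must be non-negative")
    if n_subjects and n_days and not db:
        raise ValueError("cannot generate a recall against an empty database")
    rng = _rng(seed)
    codes = [e.food_code for e in db]
    records = []
    for s in range(n_subjects):
        for d in range(n_days):
            picks = rng.integers(0, len(codes), size=foods_per_day)
            portions = rng.gamma(portion_shape, portion_scale, size=foods_per_day)
            for code_idx, grams in zip(picks, portions):
                records.append(
                    RecallRecord(
                        subject_id=f"S{s + 1:04d}",
                        day=d,
                        food_code=codes[int(code_idx)],
                        consumed_mass=float(grams),
                    )
                )
    return records
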