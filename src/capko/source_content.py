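"""Capsaicinoid-source fraction estimation from recipes and labels.

A food's capsaicinoid content is driven by how much of a capsaicinoid
source (almost always red pepper powder) it contains. That fraction is
estimated from standardized recipes (kimchi) or declared label
fractions (salted seafood, paste, convenience foods), then corrected
for processing: salted vegetables lose ~10% of their fresh weight to
draining, and fermentation degrades capsaicinoids (~20% in kimchi, ~10%
in red pepper paste).

Rounding policy (staged, matching the published tables): a
recipe-derived fraction is rounded to one decimal before cross-recipe
averaging and before the fermentation correction — that staged rounding
is what makes two napa recipes at 2.9% and 1.4% average to 2.2% and
correct to exactly 1.76%. Label-derived fractions and everything
downstream are carried at full precision, rounded only for display.
"""

from __future__ import annotations

import statistics
from typing import Mapping, Optional, Sequence

from .datamodel import LabelRecord, Recipe
from .rounding import round_half_up

__all__ = [
    "salting_weight_correction",
    "recipe_source_fraction",
    "combine_recipe_fractions",
    "fermentation_correction",
    "surrogate_lookup",
    "label_source_fraction",
    "blend_dilution",
    "composite_fraction",
    "SurrogateError",
]


class SurrogateError(KeyError):
    """A food has no surrogate mapping (and must not get one silently)."""


def salting_weight_correction(fresh_weight: float, loss: float) -> float:
    """Drained weight of a salted vegetable from its fresh weight."""
    if fresh_weight <= 0:
        raise ValueError(f"fresh weight must be positive, got {fresh_weight}")
    if not 0 <= loss < 1:
        raise ValueError(f"water loss must be in [0, 1), got {loss}")
    return fresh_weight * (1.0 - loss)


def recipe_source_fraction(
    recipe: Recipe, salting_loss: float = 0.10, rounded: bool = True
) -> float:
    """Source-ingredient percent of total ingredient weight.

    Salted ingredients are pre-corrected for draining water loss. By
    default the result is rounded to one decimal (the staged-rounding
    policy); pass ``rounded=False`` for the full-precision value.
    """
    total = 0.0
    source_weight = None
    for ing in recipe.ingredients:
        w = (
            salting_weight_correction(ing.fresh_weight, salting_loss)
            if ing.salted
            else ing.fresh_weight
        )
        total += w
        if ing.name == recipe.source_ingredient:
            source_weight = w
    if source_weight is None:
        raise ValueError(f"source ingredient missing from recipe {recipe.name!r}")
    if total <= 0:
        raise ValueError("zero total ingredient weight")
    pct = 100.0 * source_weight / total
    return round_half_up(pct, 1) if rounded else pct


def combine_recipe_fractions(fractions: Sequence[float], rounded: bool = True) -> float:
    """Average per-recipe fractions; staged rounding rounds the mean too."""
    if not fractions:
        raise ValueError("no fractions to combine")
    mean = statistics.fmean(fractions)
    return round_half_up(mean, 1) if rounded else mean


def fermentation_correction(fraction: float, loss: float) -> float:
    """Reduce a source fraction for capsaicinoid degradation (full precision)."""
    if not 0 <= loss < 1:
        raise ValueError(f"fermentation loss must be in [0, 1), got {loss}")
    return fraction * (1.0 - loss)


def surrogate_lookup(food: str, surrogates: Mapping[str, str]) -> str:
    """Donor food whose corrected fraction a recipe-less food reuses."""
    try:
        return surrogates[food]
    except KeyError:
        raise SurrogateError(
            f"no surrogate configured for {food!r}; refusing a silent default"
        ) from None


def label_source_fraction(
    products: Sequence[LabelRecord],
    source: str = "red pepper powder",
    default_pct: Optional[float] = None,
) -> tuple[float, bool]:
    """Mean declared fraction of ``source`` across product labels.

    Returns ``(percent, assumed)``: the full-precision mean of the
    declared fractions, or the configured default (``assumed=True``)
    when no label declares the source. With neither, raises.
    """
    declared = [p.fractions[source] for p in products if source in p.fractions]
    if declared:
        return statistics.fmean(declared), False
    if default_pct is not None:
        return float(default_pct), True
    raise ValueError(f"no label declares {source!r} and no default is configured")


def blend_dilution(base_fraction: float, product_share: float) -> float:
    """Source fraction after diluting the base product into a blend."""
    if not 0 < product_share <= 1:
        raise ValueError(f"product share must be in (0, 1], got {product_share}")
    return base_fraction * product_share


def composite_fraction(
    container_fraction: float, ingredient_source_fraction: float
) -> float:
    """Source percent contributed through a capsaicinoid-bearing ingredient.

    E.g. percent of red pepper powder in a dumpling = percent of kimchi
    in the dumpling x percent of red pepper powder in kimchi / 100.
    """
    if container_fraction < 0 or ingredient_source_fraction < 0:
        raise ValueError("fractions must be non-negative")
    return container_fraction * ingredient_source_fraction / 100.0
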