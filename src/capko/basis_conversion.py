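"""Dry/wet basis conversion and cultivar-level summarization.

Chili-pepper capsaicinoid measurements are published on a dry-weight or
a fresh (wet) weight basis depending on how the pepper is consumed. The
two are related by the moisture correction factor

    f = (100 - fresh water %) / (100 - dried water %),

the ratio of solid mass fractions: a dry-basis content times ``f`` is
the corresponding wet-basis content. Studies that measured only
capsaicin get dihydrocapsaicin imputed from a cultivar-specific
dihydrocapsaicin:capsaicin ratio.
"""

from __future__ import annotations

import statistics
from typing import Iterable, Sequence

from .datamodel import Basis, CompoundAmount, CultivarRecord

__all__ = [
    "moisture_correction_factor",
    "convert_basis",
    "impute_dihydrocapsaicin",
    "cultivar_summary",
    "sauce_summary",
]


def moisture_correction_factor(fresh_water_pct: float, dried_water_pct: float) -> float:
    """Dry-to-wet scaling factor from fresh and dried water contents (%)."""
    for pct in (fresh_water_pct, dried_water_pct):
        if not 0 <= pct < 100:
            raise ValueError(f"water content {pct}% outside [0, 100)")
    return (100.0 - fresh_water_pct) / (100.0 - dried_water_pct)


def convert_basis(
    amount: CompoundAmount, factor: float, target_basis: Basis | str
) -> CompoundAmount:
    """Convert an amount to the other basis via the moisture factor.

    Dry -> wet multiplies every component by ``factor``; wet -> dry
    divides. Converting to the basis the amount already carries is an
    error — it would silently apply the factor twice.
    """
    target_basis = Basis(target_basis)
    if factor <= 0:
        raise ValueError(f"moisture factor must be positive, got {factor}")
    if amount.basis is target_basis:
        raise ValueError(f"amount already on {target_basis.value} basis")
    scale = factor if target_basis is Basis.WET else 1.0 / factor
    return CompoundAmount(
        capsaicin=None if amount.capsaicin is None else amount.capsaicin * scale,
        dihydrocapsaicin=None
        if amount.dihydrocapsaicin is None
        else amount.dihydrocapsaicin * scale,
        total=amount.total * scale,
        basis=target_basis,
    )


def impute_dihydrocapsaicin(capsaicin: float, dhc_to_cap_ratio: float) -> float:
    """Estimate a missing dihydrocapsaicin level as capsaicin x ratio."""
    if capsaicin < 0 or dhc_to_cap_ratio < 0:
        raise ValueError("capsaicin and ratio must be non-negative")
    return capsaicin * dhc_to_cap_ratio


def _component_mean(values: Sequence[float | None]) -> float | None:
    present = [v for v in values if v is not None]
    return statistics.fmean(present) if present else None


def cultivar_summary(
    rows: Iterable[CultivarRecord], basis: Basis | str
) -> CompoundAmount:
    """Unweighted per-component mean over study rows on one basis.

    Components absent from a row (e.g. a study reporting only the
    combined capsaicinoid level) are skipped in that component's mean.
    Printed summary rows (``is_mean``) are excluded.
    """
    basis = Basis(basis)
    amounts = [
        (r.dry_amount if basis is Basis.DRY else r.wet_amount)
        for r in rows
        if not r.is_mean
    ]
    amounts = [a for a in amounts if a is not None]
    if not amounts:
        raise ValueError(f"no rows carry a {basis.value}-basis amount")
    return CompoundAmount.model_construct(
        capsaicin=_component_mean([a.capsaicin for a in amounts]),
        dihydrocapsaicin=_component_mean([a.dihydrocapsaicin for a in amounts]),
        total=statistics.fmean([a.total for a in amounts]),
        basis=basis,
    )


def sauce_summary(values: Sequence[float]) -> float:
    """Arithmetic mean of per-product sauce capsaicinoid contents."""
    if not values:
        raise ValueError("no values to summarize")
    return statistics.fmean(values)
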