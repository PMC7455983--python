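"""Database construction driver and import/export.

Executes the build in source order — literature summaries, the
five-level powder scale, recipe/label source fractions with processing
corrections, profile calculation, and the seasoning-assay merge — and
returns the food-entry collection together with a build report listing
per-food provenance and every correction applied. Rebuilding from
identical inputs yields a byte-identical JSON export.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import basis_conversion, calculator, source_content
from .calculator import RPP
from .datamodel import (
    Basis,
    CapsaicinoidProfile,
    FoodCategory,
    FoodEntry,
    Provenance,
    SpicinessScale,
    load_config,
    load_fixtures,
    scale_from_config,
)

__all__ = ["BuildReport", "build_database", "export_database", "import_database"]

log = logging.getLogger(__name__)


@dataclass
class BuildReport:
    """Audit trail of one database build."""

    scale_used: str = ""
    provenance: dict[str, str] = field(default_factory=dict)
    corrections: dict[str, list[str]] = field(default_factory=dict)
    validations: dict[str, dict] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    def record(self, food: str, correction: str) -> None:
        self.corrections.setdefault(food, []).append(correction)
        log.info("%s: %s", food, correction)


def _entry(
    report: BuildReport,
    code: str,
    name: str,
    category: FoodCategory,
    profile: CapsaicinoidProfile,
    provenance: Provenance,
    fractions: Optional[dict[str, float]] = None,
    assumed: bool = False,
    note: str = "",
) -> FoodEntry:
    report.provenance[name] = provenance.value
    return FoodEntry(
        food_code=code,
        name=name,
        category=category,
        source_fractions=fractions or {},
        profile=profile,
        provenance=provenance,
        assumed_default=assumed,
        note=note,
    )


def _fixed(value: float) -> CapsaicinoidProfile:
    return CapsaicinoidProfile(per_level={"fixed": value})


def _chili_entries(report: BuildReport) -> list[FoodEntry]:
    rows = load_fixtures("table1")
    by_key: dict[str, list] = {}
    for r in rows:
        if r.is_mean:
            continue
        key = (
            f"{r.cultivar}, {r.color}"
            if r.cultivar == "Korean chili pepper"
            else r.cultivar
        )
        by_key.setdefault(key, []).append(r)
    out = []
    for i, (name, grp) in enumerate(by_key.items(), start=1):
        mean = basis_conversion.cultivar_summary(grp, Basis.WET)
        out.append(
            _entry(
                report,
                f"CHI-{i:03d}",
                name,
                FoodCategory.CHILI_PEPPERS,
                _fixed(mean.total),
                Provenance.LITERATURE,
                note=f"wet-basis mean over {len(grp)} study value(s)",
            )
        )
    return out


def _powder_entry(report: BuildReport, scale: SpicinessScale) -> FoodEntry:
    return _entry(
        report,
        "PWD-001",
        "red pepper powder",
        FoodCategory.RED_PEPPER_POWDER,
        CapsaicinoidProfile(per_level=scale.mean_concentrations()),
        Provenance.LITERATURE,
        note="five-level spiciness scale means",
    )


def _hot_sauce_entries(
    report: BuildReport, config: dict
) -> tuple[list[FoodEntry], dict[str, float]]:
    df = load_fixtures("table2")
    means: dict[str, float] = {}
    for product, grp in df.groupby("product", sort=False):
        means[product] = basis_conversion.sauce_summary(list(grp["total"]))
    entries = []
    i = 1
    for product, value in means.items():
        entries.append(
            _entry(
                report,
                f"SAU-{i:03d}",
                product,
                FoodCategory.HOT_SAUCE,
                _fixed(value),
                Provenance.LITERATURE,
            )
        )
        i += 1
    for product, donor in config.get("hot_sauce_surrogates", {}).items():
        entries.append(
            _entry(
                report,
                f"SAU-{i:03d}",
                product,
                FoodCategory.HOT_SAUCE,
                _fixed(means[donor]),
                Provenance.SURROGATE,
                note=f"value of {donor}",
            )
        )
        report.record(product, f"surrogate: inherits {donor}")
        i += 1
    return entries, means


def _kimchi_entries(
    report: BuildReport, config: dict, scale: SpicinessScale
) -> tuple[list[FoodEntry], dict[str, float]]:
    recipes = load_fixtures("table3")
    salting_loss = config["salting_water_loss"]
    ferm_loss = config["fermentation_loss"]["kimchi"]

    by_food: dict[str, list[float]] = {}
    for rec in recipes:
        frac = source_content.recipe_source_fraction(
            rec, salting_loss=salting_loss, rounded=True
        )
        by_food.setdefault(rec.food, []).append(frac)
        if any(i.salted for i in rec.ingredients):
            report.record(
                rec.food, f"salting water loss {salting_loss:.0%} ({rec.name})"
            )

    corrected: dict[str, float] = {}
    for food, fracs in by_food.items():
        combined = source_content.combine_recipe_fractions(fracs, rounded=True)
        corrected[food] = source_content.fermentation_correction(combined, ferm_loss)
        report.record(
            food,
            f"recipe fraction(s) {fracs} -> mean {combined} -> "
            f"fermentation loss {ferm_loss:.0%} -> {corrected[food]:.4g}%",
        )

    surrogate_map = config["kimchi_surrogates"]
    entries = []
    i = 1
    for food, frac in corrected.items():
        entries.append(
            _entry(
                report,
                f"KIM-{i:03d}",
                food,
                FoodCategory.KIMCHI,
                calculator.profile_over_levels({RPP: frac}, scale),
                Provenance.RECIPE,
                fractions={RPP: frac},
            )
        )
        i += 1
    for food in surrogate_map:
        donor = source_content.surrogate_lookup(food, surrogate_map)
        frac = corrected[donor]
        entries.append(
            _entry(
                report,
                f"KIM-{i:03d}",
                food,
                FoodCategory.KIMCHI,
                calculator.profile_over_levels({RPP: frac}, scale),
                Provenance.SURROGATE,
                fractions={RPP: frac},
                note=f"fraction of {donor}",
            )
        )
        report.record(food, f"surrogate: inherits {donor} fraction {frac:.4g}%")
        i += 1
    return entries, corrected


def _seafood_entries(
    report: BuildReport, config: dict, scale: SpicinessScale
) -> list[FoodEntry]:
    labels = load_fixtures("table5")
    default = config["salted_seafood_default_pct"]
    exceptions = set(config["salted_seafood_default_exceptions"])
    items = list(labels) + [
        it for it in ("salted baby squid", "salted fish gill") if it not in labels
    ]
    entries = []
    for i, item in enumerate(items, start=1):
        if item in exceptions:
            frac, assumed = source_content.label_source_fraction(labels[item], RPP)
        else:
            frac, assumed = default, True
            if item in labels:
                declared, _ = source_content.label_source_fraction(labels[item], RPP)
                report.record(
                    item, f"label mean {declared:.4g}% -> default {default}% assumed"
                )
            else:
                report.record(item, f"no label data -> default {default}% assumed")
        entries.append(
            _entry(
                report,
                f"SEA-{i:03d}",
                item,
                FoodCategory.SALTED_SEAFOOD,
                calculator.profile_over_levels({RPP: frac}, scale),
                Provenance.LABEL,
                fractions={RPP: frac},
                assumed=assumed,
            )
        )
    return entries


def _paste_entries(
    report: BuildReport, config: dict, scale: SpicinessScale
) -> list[FoodEntry]:
    df = load_fixtures("table6")
    ferm_loss = config["fermentation_loss"]["red pepper paste"]
    entries = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        diluted = source_content.blend_dilution(
            float(row["label_rpp_pct"]), float(row["paste_share"])
        )
        frac = source_content.fermentation_correction(diluted, ferm_loss)
        report.record(
            str(row["product"]),
            f"label {row['label_rpp_pct']}% x share {row['paste_share']} -> "
            f"{diluted:.4g}% -> fermentation loss {ferm_loss:.0%} -> {frac:.4g}%",
        )
        entries.append(
            _entry(
                report,
                f"PAS-{i:03d}",
                str(row["product"]),
                FoodCategory.RED_PEPPER_PASTE,
                calculator.profile_over_levels({RPP: frac}, scale),
                Provenance.LABEL,
                fractions={RPP: frac},
            )
        )
    return entries


def _noodle_entries(report: BuildReport) -> list[FoodEntry]:
    assays = load_fixtures("table7")
    entries = []
    for i, a in enumerate(assays, start=1):
        per_packet = calculator.per_serving(a.total, a.packet_mass)
        entries.append(
            _entry(
                report,
                f"NDL-{i:03d}",
                f"{a.noodle_type} noodle {a.product_id}",
                FoodCategory.INSTANT_NOODLES,
                CapsaicinoidProfile(
                    per_level={"fixed": a.total},
                    per_serving={"fixed": per_packet},
                ),
                Provenance.ASSAY,
                note=f"{a.flavor}; packet {a.packet_mass} g",
            )
        )
    return entries


def _convenience_entries(
    report: BuildReport,
    config: dict,
    scale: SpicinessScale,
    kimchi_fractions: dict[str, float],
    sauce_means: dict[str, float],
) -> list[FoodEntry]:
    entries = []
    # kimchi dumplings: kimchi content from labels, red pepper powder
    # through the kimchi it contains
    dumpling_labels = load_fixtures("table8")
    kimchi_pct, _ = source_content.label_source_fraction(dumpling_labels, "kimchi")
    napa = kimchi_fractions["napa cabbage kimchi"]
    rpp_pct = source_content.composite_fraction(kimchi_pct, napa)
    report.record(
        "kimchi dumpling",
        f"kimchi label mean {kimchi_pct:.4g}% x {napa:.4g}% powder in kimchi "
        f"-> {rpp_pct:.4g}%",
    )
    entries.append(
        _entry(
            report,
            "CVF-001",
            "kimchi dumpling",
            FoodCategory.CONVENIENCE_FOODS,
            calculator.profile_over_levels({RPP: rpp_pct}, scale),
            Provenance.LABEL,
            fractions={RPP: rpp_pct, "kimchi": kimchi_pct},
        )
    )
    # spicy canned tuna: two capsaicinoid sources per product
    tuna_labels = load_fixtures("table9")
    sauce_conc = sauce_means["sweet hot chili sauce"]
    fixed = {"chili sauce": sauce_conc}
    per_product = []
    for j, lab in enumerate(tuna_labels, start=2):
        fr = {RPP: lab.fractions[RPP], "chili sauce": lab.fractions["chili sauce"]}
        per_product.append(fr)
        entries.append(
            _entry(
                report,
                f"CVF-{j:03d}",
                f"spicy canned tuna ({lab.product_id})",
                FoodCategory.CONVENIENCE_FOODS,
                calculator.profile_over_levels(fr, scale, fixed),
                Provenance.LABEL,
                fractions=fr,
            )
        )
    mean_fr = {
        k: sum(fr[k] for fr in per_product) / len(per_product)
        for k in (RPP, "chili sauce")
    }
    entries.append(
        _entry(
            report,
            f"CVF-{len(tuna_labels) + 2:03d}",
            "spicy canned tuna (mean)",
            FoodCategory.CONVENIENCE_FOODS,
            calculator.profile_over_levels(mean_fr, scale, fixed),
            Provenance.LABEL,
            fractions=mean_fr,
        )
    )
    return entries


def build_database(
    config: Optional[dict] = None,
    scale_name: Optional[str] = None,
    include_assays: bool = True,
) -> tuple[list[FoodEntry], BuildReport]:
    """Build the full food-entry collection from the packaged fixtures.

    Stages run in order: literature summaries -> spiciness scale ->
    recipe/label source fractions (with salting, fermentation, blend and
    surrogate corrections) -> level profiles -> seasoning-assay merge.
    A stage failure aborts the build with the stage named.
    """
    config = config if config is not None else load_config()
    scale = scale_from_config(config, scale_name)
    report = BuildReport(scale_used=scale_name or config["default_scale"])
    report.excluded = list(config.get("excluded_foods", []))

    entries: list[FoodEntry] = []
    stages = [
        ("chili peppers", lambda: entries.extend(_chili_entries(report))),
        ("red pepper powder", lambda: entries.append(_powder_entry(report, scale))),
    ]
    for stage, run in stages:
        try:
            run()
        except Exception as exc:
            raise RuntimeError(f"build stage {stage!r} failed: {exc}") from exc

    try:
        sauce_entries, sauce_means = _hot_sauce_entries(report, config)
        entries.extend(sauce_entries)
    except Exception as exc:
        raise RuntimeError(f"build stage 'hot sauce' failed: {exc}") from exc
    try:
        kimchi_entries, kimchi_fractions = _kimchi_entries(report, config, scale)
        entries.extend(kimchi_entries)
    except Exception as exc:
        raise RuntimeError(f"build stage 'kimchi' failed: {exc}") from exc
    try:
        entries.extend(_seafood_entries(report, config, scale))
    except Exception as exc:
        raise RuntimeError(f"build stage 'salted seafood' failed: {exc}") from exc
    try:
        entries.extend(_paste_entries(report, config, scale))
    except Exception as exc:
        raise RuntimeError(f"build stage 'red pepper paste' failed: {exc}") from exc
    if include_assays:
        try:
            entries.extend(_noodle_entries(report))
        except Exception as exc:
            raise RuntimeError(f"build stage 'instant noodles' failed: {exc}") from exc
    try:
        entries.extend(
            _convenience_entries(report, config, scale, kimchi_fractions, sauce_means)
        )
    except Exception as exc:
        raise RuntimeError(f"build stage 'convenience foods' failed: {exc}") from exc

    # published-range validation of the two foods with measured ranges
    by_name = {e.name: e for e in entries}
    for food, rng in config.get("validation_ranges", {}).items():
        if food in by_name:
            res = calculator.validate_range(
                by_name[food].profile, (rng["lower"], rng["upper"])
            )
            report.validations[food] = {
                "interval": list(res.interval),
                "passed": res.passed,
                "levels_inside": sorted(res.inside),
            }
    return entries, report


def export_database(
    db: Sequence[FoodEntry],
    format: str = "json",
    report: Optional[BuildReport] = None,
) -> str:
    """Serialize the database deterministically.

    ``json`` nests full-precision values plus the build report;
    ``delimited`` is a flat CSV with full-precision and display-rounded
    (2 dp) content columns side by side.
    """
    if format == "json":
        doc = {"foods": [e.model_dump(mode="json") for e in db]}
        if report is not None:
            doc["report"] = {
                "scale_used": report.scale_used,
                "provenance": report.provenance,
                "corrections": report.corrections,
                "validations": report.validations,
                "excluded": report.excluded,
            }
        # insertion order is deterministic and meaningful (level order),
        # so keys are not sorted
        return json.dumps(doc, indent=1)
    if format == "delimited":
        import csv
        import io

        from .rounding import round_half_up

        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(
            ["food_code", "name", "category", "provenance", "level",
             "mg_per_100g", "mg_per_100g_2dp"]
        )
        for e in db:
            for level, v in e.profile.per_level.items():
                w.writerow(
                    [e.food_code, e.name, e.category.value, e.provenance.value,
                     level, repr(v), round_half_up(v, 2)]
                )
        return buf.getvalue()
    raise ValueError(f"unknown export format {format!r}")


def import_database(text: str) -> list[FoodEntry]:
    """Re-validate and load a JSON export produced by :func:`export_database`."""
    doc = json.loads(text)
    return [FoodEntry(**d) for d in doc["foods"]]
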