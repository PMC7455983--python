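"""Domain types for the capsaicinoid food-composition database.

Every quantity is milligrams of capsaicinoid (capsaicin +
dihydrocapsaicin) per 100 g of material unless a field says otherwise.
Amounts carry an explicit basis (dry or wet/as-consumed weight) because
mixing bases silently is the classic composition-table error; arithmetic
across bases is rejected at the type level.

The module also ships the in-package fixture tables (transcribed printed
values, rounded as printed) and :func:`load_fixtures`, the single entry
point every other module uses to obtain validated records.
"""

from __future__ import annotations

import enum
import math
from importlib import resources
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "Basis",
    "FoodCategory",
    "Provenance",
    "CompoundAmount",
    "CultivarRecord",
    "LiteratureValue",
    "SpicinessLevel",
    "SpicinessScale",
    "Ingredient",
    "Recipe",
    "LabelRecord",
    "CapsaicinoidProfile",
    "FoodEntry",
    "StandardCurve",
    "SeasoningAssay",
    "RecallRecord",
    "FixtureError",
    "load_fixtures",
    "load_config",
]

#: printed fixture values carry two decimals; "approximately equal"
#: checks on them allow half a unit in the last printed place, doubled
#: where two rounded addends meet (total vs. cap + dhc).
PRINTED_TOL = 0.02


class FixtureError(ValueError):
    """Raised when a fixture is unknown or a row violates an invariant."""


class Basis(str, enum.Enum):
    DRY = "dry"
    WET = "wet"


class FoodCategory(str, enum.Enum):
    """The eight food categories of the database."""

    CHILI_PEPPERS = "chili peppers"
    RED_PEPPER_POWDER = "red pepper powder"
    HOT_SAUCE = "hot sauce"
    KIMCHI = "kimchi"
    SALTED_SEAFOOD = "salted seafood"
    RED_PEPPER_PASTE = "red pepper paste"
    INSTANT_NOODLES = "instant noodles"
    CONVENIENCE_FOODS = "other convenience foods"


class Provenance(str, enum.Enum):
    """How a food's capsaicinoid content was established."""

    LITERATURE = "literature"
    RECIPE = "recipe"
    LABEL = "label"
    ASSAY = "assay"
    SURROGATE = "surrogate"


class CompoundAmount(BaseModel):
    """Capsaicin / dihydrocapsaicin / total content on a declared basis.

    ``capsaicin`` and ``dihydrocapsaicin`` may be absent (some studies
    report only the combined capsaicinoid level); when both are present
    the total must agree with their sum to printed-rounding tolerance.
    """

    capsaicin: Optional[float] = Field(default=None, ge=0)
    dihydrocapsaicin: Optional[float] = Field(default=None, ge=0)
    total: float = Field(ge=0)
    basis: Basis

    @model_validator(mode="after")
    def _check_sum(self) -> "CompoundAmount":
        if self.capsaicin is not None and self.dihydrocapsaicin is not None:
            if abs(self.total - (self.capsaicin + self.dihydrocapsaicin)) > PRINTED_TOL:
                raise ValueError(
                    f"total {self.total} inconsistent with capsaicin "
                    f"{self.capsaicin} + dihydrocapsaicin {self.dihydrocapsaicin}"
                )
        return self


class CultivarRecord(BaseModel):
    """One study's capsaicinoid measurement of a chili-pepper cultivar."""

    cultivar: str
    color: str = ""
    citation: str = ""
    is_mean: bool = False
    dhc_imputed: bool = False
    dry_amount: Optional[CompoundAmount] = None
    wet_amount: Optional[CompoundAmount] = None
    moisture_factor: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "CultivarRecord":
        if self.dry_amount is None and self.wet_amount is None:
            raise ValueError("at least one of dry_amount/wet_amount required")
        if self.dry_amount is not None and self.dry_amount.basis is not Basis.DRY:
            raise ValueError("dry_amount must carry dry basis")
        if self.wet_amount is not None and self.wet_amount.basis is not Basis.WET:
            raise ValueError("wet_amount must carry wet basis")
        if (
            self.dry_amount is not None
            and self.wet_amount is not None
            and self.moisture_factor is not None
        ):
            expect = self.dry_amount.total * self.moisture_factor
            if abs(self.wet_amount.total - expect) > PRINTED_TOL:
                raise ValueError(
                    f"wet total {self.wet_amount.total} != dry total "
                    f"{self.dry_amount.total} x factor {self.moisture_factor}"
                )
        return self


class LiteratureValue(BaseModel):
    """A single published red-pepper-powder capsaicinoid content."""

    value: float = Field(gt=0)
    study_id: str = ""


class SpicinessLevel(BaseModel):
    name: str
    lower: float = Field(ge=0)
    upper: float
    mean_conc: float

    @model_validator(mode="after")
    def _check(self) -> "SpicinessLevel":
        if not self.lower <= self.upper:
            raise ValueError(f"level {self.name}: lower > upper")
        if not self.lower <= self.mean_conc <= self.upper:
            raise ValueError(f"level {self.name}: mean_conc outside range")
        return self


class SpicinessScale(BaseModel):
    """Ordered ladder of red-pepper-powder concentration levels.

    The default database scale has exactly five levels (mild through
    extremely hot); partially built scales with another count are legal
    so that level means can be populated incrementally.
    """

    levels: list[SpicinessLevel]

    @model_validator(mode="after")
    def _check(self) -> "SpicinessScale":
        for a, b in zip(self.levels, self.levels[1:]):
            if not a.upper < b.lower:
                raise ValueError(f"levels {a.name}/{b.name} overlap or touch")
        return self

    @property
    def names(self) -> list[str]:
        return [lv.name for lv in self.levels]

    def level(self, name: str) -> SpicinessLevel:
        for lv in self.levels:
            if lv.name == name:
                return lv
        raise KeyError(name)

    def mean_concentrations(self) -> dict[str, float]:
        return {lv.name: lv.mean_conc for lv in self.levels}


class Ingredient(BaseModel):
    name: str
    fresh_weight: float = Field(gt=0)
    salted: bool = False


class Recipe(BaseModel):
    """A standardized recipe with one designated capsaicinoid source."""

    name: str
    food: str = ""
    ingredients: list[Ingredient]
    source_ingredient: str = "red pepper powder"
    fermentation_loss: float = Field(default=0.0, ge=0, lt=1)
    citation: str = ""

    @model_validator(mode="after")
    def _check(self) -> "Recipe":
        n = sum(1 for i in self.ingredients if i.name == self.source_ingredient)
        if n != 1:
            raise ValueError(
                f"source ingredient {self.source_ingredient!r} occurs {n} times"
            )
        return self


class LabelRecord(BaseModel):
    """Declared capsaicinoid-source fractions from one product label."""

    product_id: str
    fractions: dict[str, float] = Field(default_factory=dict)
    serving_mass: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "LabelRecord":
        for k, v in self.fractions.items():
            if not 0 <= v <= 100:
                raise ValueError(f"fraction {k}={v} outside [0, 100]")
        if sum(self.fractions.values()) > 100 + 1e-9:
            raise ValueError("declared fractions exceed 100%")
        return self


class CapsaicinoidProfile(BaseModel):
    """Per-level capsaicinoid content of a food (mg/100 g, wet basis).

    Foods with a single published value (no spiciness structure) use a
    degenerate one-level profile so downstream arithmetic is uniform.
    """

    per_level: dict[str, float]
    per_serving: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "CapsaicinoidProfile":
        vals = list(self.per_level.values())
        if any(v < 0 for v in vals):
            raise ValueError("negative content")
        if any(b < a - 1e-9 for a, b in zip(vals, vals[1:])):
            raise ValueError("profile not monotone over ordered levels")
        if self.per_serving is not None and any(
            v < 0 for v in self.per_serving.values()
        ):
            raise ValueError("negative per-serving content")
        return self

    @property
    def is_fixed(self) -> bool:
        return len(self.per_level) == 1

    def content(self, level: Optional[str] = None) -> float:
        """Content at ``level``, or the single value of a fixed profile."""
        if self.is_fixed:
            return next(iter(self.per_level.values()))
        if level is None:
            raise ValueError("level required for a multi-level profile")
        return self.per_level[level]


class FoodEntry(BaseModel):
    """One database record: a food and its capsaicinoid profile."""

    food_code: str
    name: str
    category: FoodCategory
    source_fractions: dict[str, float] = Field(default_factory=dict)
    profile: CapsaicinoidProfile
    provenance: Provenance
    assumed_default: bool = False
    note: str = ""


class StandardCurve(BaseModel):
    """Fitted calibration line: peak area = slope * (ug/ml) + intercept."""

    slope: float = Field(gt=0)
    intercept: float
    r_squared: float = Field(ge=0, le=1)


class SeasoningAssay(BaseModel):
    """HPLC result for one instant-noodle seasoning packet."""

    product_id: str
    noodle_type: str = "regular"
    flavor: str = ""
    form: str = "powder"
    capsaicin: float = Field(ge=0)
    capsaicin_sd: float = Field(default=0.0, ge=0)
    dihydrocapsaicin: float = Field(ge=0)
    dihydrocapsaicin_sd: float = Field(default=0.0, ge=0)
    total: float = Field(ge=0)
    total_sd: float = Field(default=0.0, ge=0)
    packet_mass: float = Field(gt=0)
    per_packet: float = Field(ge=0)
    per_packet_sd: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SeasoningAssay":
        # per-packet column is printed at 2 dp; recomputation must agree
        # to half a unit in the last place
        expect = self.total * self.packet_mass / 100.0
        if abs(self.per_packet - expect) > 0.01:
            raise ValueError(
                f"{self.product_id}: per-packet {self.per_packet} inconsistent "
                f"with {self.total} mg/100 g x {self.packet_mass} g"
            )
        return self


class RecallRecord(BaseModel):
    """One consumed food in a 24-hour dietary recall."""

    subject_id: str
    day: int = Field(ge=0)
    food_code: str
    consumed_mass: float = Field(ge=0)


# ---------------------------------------------------------------------------
# fixture loading


def _fixture_path(name: str):
    return resources.files("capko.fixtures").joinpath(name)


def _read_csv(name: str) -> pd.DataFrame:
    path = _fixture_path(name)
    with resources.as_file(path) as p:
        if p.stat().st_size == 0:
            return pd.DataFrame()
        return pd.read_csv(p)


def load_config(path: Optional[str] = None) -> dict:
    """Load the build configuration (packaged default or an override file)."""
    if path is None:
        text = _fixture_path("config.yaml").read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return yaml.safe_load(text)


def scale_from_config(config: dict, which: Optional[str] = None) -> SpicinessScale:
    """Build a :class:`SpicinessScale` from a configuration mapping."""
    which = which or config["default_scale"]
    return SpicinessScale(levels=[SpicinessLevel(**lv) for lv in config["scales"][which]])


def _float_or_none(x) -> Optional[float]:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)


def _load_table1(df: pd.DataFrame) -> list[CultivarRecord]:
    out = []
    for idx, row in df.iterrows():
        try:
            dry = None
            if _float_or_none(row["total_dry"]) is not None:
                dry = CompoundAmount(
                    capsaicin=_float_or_none(row["capsaicin_dry"]),
                    dihydrocapsaicin=_float_or_none(row["dihydrocapsaicin_dry"]),
                    total=float(row["total_dry"]),
                    basis=Basis.DRY,
                )
            wet = None
            if _float_or_none(row["total_wet"]) is not None:
                wet = CompoundAmount(
                    capsaicin=_float_or_none(row["capsaicin_wet"]),
                    dihydrocapsaicin=_float_or_none(row["dihydrocapsaicin_wet"]),
                    total=float(row["total_wet"]),
                    basis=Basis.WET,
                )
            out.append(
                CultivarRecord(
                    cultivar=str(row["cultivar"]),
                    color=str(row["color"]),
                    citation=str(row["study"]),
                    is_mean=bool(row["is_mean"]),
                    dhc_imputed=bool(row["dhc_imputed"]),
                    dry_amount=dry,
                    wet_amount=wet,
                    moisture_factor=_float_or_none(row["moisture_factor"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise FixtureError(f"table1 row {idx}: {exc}") from exc
    return out


def _load_table3(df: pd.DataFrame) -> list[Recipe]:
    out = []
    for name, grp in df.groupby("recipe", sort=False):
        try:
            sources = grp.loc[grp["is_source"] == 1, "ingredient"]
            out.append(
                Recipe(
                    name=str(name),
                    food=str(grp["food"].iloc[0]),
                    ingredients=[
                        Ingredient(
                            name=str(r["ingredient"]),
                            fresh_weight=float(r["fresh_weight_g"]),
                            salted=bool(r["salted"]),
                        )
                        for _, r in grp.iterrows()
                    ],
                    source_ingredient=str(sources.iloc[0]) if len(sources) else "",
                    citation=str(grp["study"].iloc[0]),
                )
            )
        except (ValueError, IndexError) as exc:
            raise FixtureError(f"table3 recipe {name!r}: {exc}") from exc
    return out


def _load_table5(df: pd.DataFrame) -> dict[str, list[LabelRecord]]:
    out: dict[str, list[LabelRecord]] = {}
    for idx, row in df.iterrows():
        try:
            rec = LabelRecord(
                product_id=f"{row['item']} #{int(row['product_no'])}",
                fractions={"red pepper powder": float(row["rpp_pct"])},
            )
        except ValueError as exc:
            raise FixtureError(f"table5 row {idx}: {exc}") from exc
        out.setdefault(str(row["item"]), []).append(rec)
    return out


def _load_table7(df: pd.DataFrame) -> list[SeasoningAssay]:
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                SeasoningAssay(
                    product_id=str(row["brand"]),
                    noodle_type=str(row["noodle_type"]),
                    flavor=str(row["flavor"]),
                    form=str(row["form"]),
                    capsaicin=float(row["capsaicin"]),
                    capsaicin_sd=float(row["capsaicin_sd"]),
                    dihydrocapsaicin=float(row["dihydrocapsaicin"]),
                    dihydrocapsaicin_sd=float(row["dihydrocapsaicin_sd"]),
                    total=float(row["total"]),
                    total_sd=float(row["total_sd"]),
                    packet_mass=float(row["packet_g"]),
                    per_packet=float(row["per_packet"]),
                    per_packet_sd=float(row["per_packet_sd"]),
                )
            )
        except ValueError as exc:
            raise FixtureError(f"table7 row {idx}: {exc}") from exc
    return out


def _load_table8(df: pd.DataFrame) -> list[LabelRecord]:
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                LabelRecord(
                    product_id=f"{row['manufacturer']} #{int(row['product_no'])}",
                    fractions={"kimchi": float(row["kimchi_pct"])},
                )
            )
        except ValueError as exc:
            raise FixtureError(f"table8 row {idx}: {exc}") from exc
    return out


def _load_table9(df: pd.DataFrame) -> list[LabelRecord]:
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                LabelRecord(
                    product_id=str(row["manufacturer"]),
                    fractions={
                        "red pepper powder": float(row["rpp_pct"]),
                        "chili sauce": float(row["chili_sauce_pct"]),
                    },
                )
            )
        except ValueError as exc:
            raise FixtureError(f"table9 row {idx}: {exc}") from exc
    return out


_LOADERS = {
    "table1": ("table1.csv", _load_table1),
    "table2": ("table2.csv", lambda df: df),
    "table3": ("table3.csv", _load_table3),
    "table5": ("table5.csv", _load_table5),
    "table6": ("table6.csv", lambda df: df),
    "table7": ("table7.csv", _load_table7),
    "table8": ("table8.csv", _load_table8),
    "table9": ("table9.csv", _load_table9),
}


def load_fixtures(fixture_name: str):
    """Load and validate one packaged fixture table.

    Parameters
    ----------
    fixture_name
        One of ``table1``, ``table2``, ``table3``, ``table5``–``table9``
        or ``config``. (There is no "table4": that table of the source
        material is entirely derived and is recomputed, never stored.)

    Returns
    -------
    A validated, typed collection: cultivar records (table1), a hot-sauce
    DataFrame (table2), recipes (table3), label records per item
    (table5/8/9), a paste-blend DataFrame (table6), seasoning assays
    (table7) or the configuration mapping.

    Raises
    ------
    FixtureError
        If the fixture name is unknown or any row violates an invariant
        (the error message names the row and offending field).
    """
    if fixture_name == "config":
        return load_config()
    try:
        fname, loader = _LOADERS[fixture_name]
    except KeyError:
        raise FixtureError(
            f"unknown fixture {fixture_name!r}; expected one of "
            f"{sorted(_LOADERS)} or 'config'"
        ) from None
    df = _read_csv(fname)
    if df.empty:
        return [] if fixture_name != "table5" else {}
    return loader(df)
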