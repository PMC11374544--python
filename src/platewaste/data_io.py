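"""Domain types plus reading/writing of every campaign table.

A *campaign directory* holds the delimited inputs consumed by all pipeline
stages (UTF-8, comma delimiter, ``.`` decimal separator):

``observations.csv``
    one row per day x school x food category aggregate weighing:
    ``date,school_id,case_id,category,waste_mass_g,children_served,season``
``menus.csv``
    which dishes were offered: ``date,school_id,dish_id``
``dishes.csv``
    dish library with the three weighed servings:
    ``dish_id,name,category,serving1_g,serving2_g,serving3_g,avg_serving_g``
``recipes.csv``
    ``dish_id,food_item_id,grams_per_serving`` (edible grams per serving)
``composition.csv``
    ``food_item_id`` plus one column per :data:`~platewaste.nutrients.COMPONENTS`
    entry, per 100 g edible food
``factors.csv``
    ``scope,production_ef_kgco2e_per_kg,transport_ef_kgco2e_per_kg_km,``
    ``disposal_ef_kgco2e_per_kg`` where *scope* is a food item id, a category
    code, or ``disposal:<method>``
``prices.csv``
    ``scope,price_eur_per_kg`` (item id or category code)
``guidelines.csv``
    ``quantity,lower,upper,units,basis``
``config.yaml``
    campaign metadata (cases, distances, prices paid, disposal method)

Item-level factor/price rows override category-level rows, field by field.
Masses are grams everywhere internally; kilograms appear only in report
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    IntegrityError,
    SchemaError,
    ValidationError,
)
from .nutrients import COMPONENTS, COMPONENT_UNITS, NutrientProfile


class FoodCategory(str, Enum):
    """The seven aggregate-weighing bins.

    ``OTHER`` is reserved for mixed starch/protein dishes such as pizza.
    """

    STARCHY = "starchy"
    BREAD = "bread"
    PROTEIN = "protein"
    VEGETABLE = "vegetable"
    FRUIT = "fruit"
    DESSERT = "dessert"
    OTHER = "other"


CATEGORY_CODES: tuple[str, ...] = tuple(c.value for c in FoodCategory)

#: Guideline quantities derived from the profile rather than read off it:
#: share of energy provided by each macronutrient (Atwater 4/9/4 kcal per g).
DERIVED_QUANTITIES: tuple[str, ...] = (
    "protein_energy_pct",
    "fat_energy_pct",
    "carbohydrate_energy_pct",
)


def as_category(code: str | FoodCategory) -> FoodCategory:
    try:
        return FoodCategory(code)
    except ValueError:
        raise ValidationError(
            f"unknown food category {code!r}; expected one of {CATEGORY_CODES}"
        ) from None


@dataclass(frozen=True)
class DishServing:
    """A dish with its recipe and the measured average edible serving."""

    dish_id: str
    name: str
    category: FoodCategory
    serving_measurements_g: tuple[float, float, float]
    avg_serving_g: float
    recipe: tuple[tuple[str, float], ...]  # (food_item_id, edible grams/serving)

    def __post_init__(self) -> None:
        if len(self.serving_measurements_g) != 3:
            raise ValidationError(
                f"dish {self.dish_id}: exactly 3 serving measurements required"
            )
        if any(m <= 0 for m in self.serving_measurements_g):
            raise ValidationError(f"dish {self.dish_id}: serving measurements must be > 0")
        mean = sum(self.serving_measurements_g) / 3.0
        if not math.isclose(self.avg_serving_g, mean, rel_tol=1e-9, abs_tol=0.0):
            raise ValidationError(
                f"dish {self.dish_id}: avg_serving_g {self.avg_serving_g} is not the "
                f"mean of the measurements ({mean})"
            )
        if any(g < 0 for _, g in self.recipe):
            raise ValidationError(f"dish {self.dish_id}: negative recipe grams")
        if sum(g for _, g in self.recipe) <= 0:
            raise ValidationError(f"dish {self.dish_id}: recipe grams must sum > 0")


@dataclass(frozen=True)
class CompositionRecord:
    """Nutrient profile of one food item per 100 g edible food."""

    food_item_id: str
    profile_per_100g: NutrientProfile


@dataclass(frozen=True)
class FactorRow:
    production_ef: Optional[float] = None  # kg CO2e per kg
    transport_ef: Optional[float] = None  # kg CO2e per kg per km
    price: Optional[float] = None  # EUR per kg


class FactorTable:
    """Emission factors and market prices with item-over-category resolution."""

    def __init__(
        self,
        rows: Mapping[str, FactorRow],
        disposal_ef: Mapping[str, float],
    ) -> None:
        for scope, row in rows.items():
            for name in ("production_ef", "transport_ef", "price"):
                value = getattr(row, name)
                if value is not None and value < 0:
                    raise ValidationError(f"factor {name} for {scope!r} is negative")
        for method, ef in disposal_ef.items():
            if ef < 0:
                raise ValidationError(f"disposal factor for {method!r} is negative")
        self._rows = dict(rows)
        self._disposal = dict(disposal_ef)

    @property
    def rows(self) -> dict[str, FactorRow]:
        return dict(self._rows)

    @property
    def disposal_factors(self) -> dict[str, float]:
        return dict(self._disposal)

    def _resolve(self, field_name: str, item_id: str, category: FoodCategory) -> float:
        for scope in (item_id, category.value):
            row = self._rows.get(scope)
            if row is not None:
                value = getattr(row, field_name)
                if value is not None:
                    return float(value)
        raise IntegrityError(
            f"no {field_name} for item {item_id!r} (category {category.value!r})"
        )

    def production_ef(self, item_id: str, category: FoodCategory) -> float:
        return self._resolve("production_ef", item_id, category)

    def transport_ef(self, item_id: str, category: FoodCategory) -> float:
        return self._resolve("transport_ef", item_id, category)

    def price(self, item_id: str, category: FoodCategory) -> float:
        return self._resolve("price", item_id, category)

    def disposal_ef(self, method: str) -> float:
        try:
            return self._disposal[method]
        except KeyError:
            raise ConfigurationError(
                f"no disposal factor for method {method!r}; "
                f"known methods: {sorted(self._disposal)}"
            ) from None


@dataclass(frozen=True)
class GuidelineBound:
    quantity: str
    lower: Optional[float]
    upper: Optional[float]
    units: str
    basis: str = "both"  # as_served | as_consumed | both

    def __post_init__(self) -> None:
        if self.quantity not in COMPONENTS and self.quantity not in DERIVED_QUANTITIES:
            raise ValidationError(f"unknown guideline quantity {self.quantity!r}")
        if self.lower is None and self.upper is None:
            raise ValidationError(f"bound for {self.quantity!r} has neither limit")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValidationError(
                f"bound for {self.quantity!r}: lower {self.lower} > upper {self.upper}"
            )
        expected = (
            "pct" if self.quantity in DERIVED_QUANTITIES else COMPONENT_UNITS[self.quantity]
        )
        if self.units != expected:
            raise ConfigurationError(
                f"bound for {self.quantity!r} declared in {self.units!r}; "
                f"profiles carry {expected!r}"
            )
        if self.basis not in ("as_served", "as_consumed", "both"):
            raise ValidationError(f"unknown basis {self.basis!r}")


class GuidelineBounds:
    """Ordered collection of guideline bounds with per-quantity lookup."""

    def __init__(self, bounds: Iterable[GuidelineBound]) -> None:
        self._bounds = list(bounds)
        seen: set[str] = set()
        for b in self._bounds:
            if b.quantity in seen:
                raise ValidationError(f"duplicate guideline row for {b.quantity!r}")
            seen.add(b.quantity)

    def __iter__(self):
        return iter(self._bounds)

    def __len__(self) -> int:
        return len(self._bounds)

    def get(self, quantity: str) -> Optional[GuidelineBound]:
        for b in self._bounds:
            if b.quantity == quantity:
                return b
        return None


@dataclass(frozen=True)
class CaseConfig:
    case_id: str
    transport_distance_km: float = 0.0
    full_price_eur: Optional[float] = None
    procurement_budget_eur: Optional[float] = None
    meals_served: Optional[int] = None  # defaults to total children-lunches


@dataclass(frozen=True)
class CampaignConfig:
    cases: tuple[CaseConfig, ...]
    disposal_method: str = "composting"

    def case(self, case_id: str) -> CaseConfig:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise ConfigurationError(f"case {case_id!r} not declared in configuration")

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(c.case_id for c in self.cases)


OBSERVATION_COLUMNS = (
    "date",
    "school_id",
    "case_id",
    "category",
    "waste_mass_g",
    "children_served",
    "season",
)


@dataclass
class Campaign:
    """A fully cross-validated dataset: everything the pipeline stages need."""

    observations: pd.DataFrame
    menus: pd.DataFrame
    dishes: dict[str, DishServing]
    composition: dict[str, CompositionRecord]
    factors: FactorTable
    guidelines: GuidelineBounds
    config: CampaignConfig

    @property
    def case_ids(self) -> tuple[str, ...]:
        return self.config.case_ids

    def dates(self, case_id: str) -> list[str]:
        mask = self.observations["case_id"] == case_id
        return sorted(self.observations.loc[mask, "date"].unique())

    def dishes_on(self, date: str, school_id: str) -> list[DishServing]:
        mask = (self.menus["date"] == date) & (self.menus["school_id"] == school_id)
        return [self.dishes[d] for d in self.menus.loc[mask, "dish_id"]]

    def equals(self, other: "Campaign") -> bool:
        """Exact equality on every table and every numeric field."""
        obs_a = self.observations.sort_values(list(OBSERVATION_COLUMNS)).reset_index(drop=True)
        obs_b = other.observations.sort_values(list(OBSERVATION_COLUMNS)).reset_index(drop=True)
        menus_a = self.menus.sort_values(["date", "school_id", "dish_id"]).reset_index(drop=True)
        menus_b = other.menus.sort_values(["date", "school_id", "dish_id"]).reset_index(drop=True)
        return (
            obs_a.equals(obs_b)
            and menus_a.equals(menus_b)
            and self.dishes == other.dishes
            and self.composition == other.composition
            and self.factors.rows == other.factors.rows
            and self.factors.disposal_factors == other.factors.disposal_factors
            and list(self.guidelines) == list(other.guidelines)
            and self.config == other.config
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    return frame


def _to_float(frame: pd.DataFrame, column: str, source: str) -> pd.Series:
    try:
        return frame[column].astype(float)
    except ValueError as exc:
        raise SchemaError(f"{source}: non-numeric value in column {column!r}: {exc}") from exc


def _optional_float(raw: str) -> Optional[float]:
    raw = raw.strip()
    return None if raw == "" else float(raw)


def load_observations(path: Path) -> pd.DataFrame:
    frame = _read_csv(path, [c for c in OBSERVATION_COLUMNS if c != "season"])
    if "season" not in frame.columns:
        frame["season"] = ""
    frame = frame[list(OBSERVATION_COLUMNS)].copy()
    frame["waste_mass_g"] = _to_float(frame, "waste_mass_g", path.name)
    frame["children_served"] = _to_float(frame, "children_served", path.name).astype(int)
    if (frame["waste_mass_g"] < 0).any():
        bad = frame.loc[frame["waste_mass_g"] < 0]
        raise ValidationError(
            f"{path.name}: negative waste mass in rows {bad.index.tolist()}"
        )
    if (frame["children_served"] < 1).any():
        raise ValidationError(f"{path.name}: children_served must be >= 1")
    frame["category"].map(as_category)  # raises on unknown codes
    dup = frame.duplicated(subset=["date", "school_id", "category"])
    if dup.any():
        keys = frame.loc[dup, ["date", "school_id", "category"]].to_dict("records")
        raise ValidationError(f"duplicate (date, school, category) rows: {keys}")
    return frame


def load_menus(path: Path) -> pd.DataFrame:
    frame = _read_csv(path, ["date", "school_id", "dish_id"])
    return frame[["date", "school_id", "dish_id"]].copy()


def load_dishes(dishes_path: Path, recipes_path: Path) -> dict[str, DishServing]:
    dishes = _read_csv(
        dishes_path,
        ["dish_id", "name", "category", "serving1_g", "serving2_g", "serving3_g", "avg_serving_g"],
    )
    recipes = _read_csv(recipes_path, ["dish_id", "food_item_id", "grams_per_serving"])
    recipes["grams_per_serving"] = _to_float(recipes, "grams_per_serving", recipes_path.name)
    by_dish: dict[str, list[tuple[str, float]]] = {}
    for row in recipes.itertuples(index=False):
        by_dish.setdefault(row.dish_id, []).append((row.food_item_id, float(row.grams_per_serving)))

    out: dict[str, DishServing] = {}
    for row in dishes.itertuples(index=False):
        if row.dish_id in out:
            raise ValidationError(f"duplicate dish_id {row.dish_id!r}")
        if row.dish_id not in by_dish:
            raise IntegrityError(f"dish {row.dish_id!r} has no recipe rows")
        out[row.dish_id] = DishServing(
            dish_id=row.dish_id,
            name=row.name,
            category=as_category(row.category),
            serving_measurements_g=(
                float(row.serving1_g),
                float(row.serving2_g),
                float(row.serving3_g),
            ),
            avg_serving_g=float(row.avg_serving_g),
            recipe=tuple(by_dish[row.dish_id]),
        )
    dangling = set(by_dish) - set(out)
    if dangling:
        raise IntegrityError(f"recipe rows for unknown dish ids: {sorted(dangling)}")
    return out


def load_composition(path: Path) -> dict[str, CompositionRecord]:
    frame = _read_csv(path, ["food_item_id", *COMPONENTS])
    out: dict[str, CompositionRecord] = {}
    for _, row in frame.iterrows():
        item = row["food_item_id"]
        if item in out:
            raise ValidationError(f"duplicate composition record for {item!r}")
        profile = NutrientProfile.from_mapping(
            {name: float(row[name]) for name in COMPONENTS}
        )
        out[item] = CompositionRecord(food_item_id=item, profile_per_100g=profile)
    return out


def load_factors(factors_path: Path, prices_path: Path) -> FactorTable:
    factors = _read_csv(
        factors_path,
        ["scope", "production_ef_kgco2e_per_kg", "transport_ef_kgco2e_per_kg_km",
         "disposal_ef_kgco2e_per_kg"],
    )
    prices = _read_csv(prices_path, ["scope", "price_eur_per_kg"])

    rows: dict[str, FactorRow] = {}
    disposal: dict[str, float] = {}
    for row in factors.itertuples(index=False):
        scope = row.scope
        if scope.startswith("disposal:"):
            ef = _optional_float(row.disposal_ef_kgco2e_per_kg)
            if ef is None:
                raise SchemaError(f"disposal row {scope!r} lacks a disposal factor")
            disposal[scope.split(":", 1)[1]] = ef
            continue
        if scope in rows:
            raise ValidationError(f"duplicate factor row for scope {scope!r}")
        rows[scope] = FactorRow(
            production_ef=_optional_float(row.production_ef_kgco2e_per_kg),
            transport_ef=_optional_float(row.transport_ef_kgco2e_per_kg_km),
        )
    for row in prices.itertuples(index=False):
        price = _optional_float(row.price_eur_per_kg)
        if price is None:
            raise SchemaError(f"prices: empty price for scope {row.scope!r}")
        current = rows.get(row.scope, FactorRow())
        if current.price is not None:
            raise ValidationError(f"duplicate price row for scope {row.scope!r}")
        rows[row.scope] = FactorRow(
            production_ef=current.production_ef,
            transport_ef=current.transport_ef,
            price=price,
        )
    return FactorTable(rows, disposal)


def load_guidelines(path: Path) -> GuidelineBounds:
    frame = _read_csv(path, ["quantity", "lower", "upper", "units"])
    if "basis" not in frame.columns:
        frame["basis"] = "both"
    bounds = [
        GuidelineBound(
            quantity=row.quantity,
            lower=_optional_float(row.lower),
            upper=_optional_float(row.upper),
            units=row.units,
            basis=row.basis or "both",
        )
        for row in frame.itertuples(index=False)
    ]
    return GuidelineBounds(bounds)


def load_config(path: Path) -> CampaignConfig:
    if not path.exists():
        raise SchemaError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if "cases" not in raw or not raw["cases"]:
        raise SchemaError("config.yaml: missing required key 'cases'")
    cases = []
    for entry in raw["cases"]:
        if "case_id" not in entry:
            raise SchemaError("config.yaml: case entry without case_id")
        cases.append(
            CaseConfig(
                case_id=str(entry["case_id"]),
                transport_distance_km=float(entry.get("transport_distance_km", 0.0)),
                full_price_eur=(
                    float(entry["full_price_eur"])
                    if entry.get("full_price_eur") is not None
                    else None
                ),
                procurement_budget_eur=(
                    float(entry["procurement_budget_eur"])
                    if entry.get("procurement_budget_eur") is not None
                    else None
                ),
                meals_served=(
                    int(entry["meals_served"])
                    if entry.get("meals_served") is not None
                    else None
                ),
            )
        )
    return CampaignConfig(
        cases=tuple(cases),
        disposal_method=str(raw.get("disposal_method", "composting")),
    )


FILE_NAMES = {
    "observations": "observations.csv",
    "menus": "menus.csv",
    "dishes": "dishes.csv",
    "recipes": "recipes.csv",
    "composition": "composition.csv",
    "factors": "factors.csv",
    "prices": "prices.csv",
    "guidelines": "guidelines.csv",
    "config": "config.yaml",
}


def load_campaign(data_dir: str | Path) -> Campaign:
    """Load and cross-validate a full campaign directory.

    Raises
    ------
    SchemaError
        for missing files/columns or malformed cells.
    IntegrityError
        for dangling cross-references, listing the offending ids.
    ValidationError
        for invariant violations (negative masses, duplicate keys, ...).
    """
    data_dir = Path(data_dir)
    campaign = Campaign(
        observations=load_observations(data_dir / FILE_NAMES["observations"]),
        menus=load_menus(data_dir / FILE_NAMES["menus"]),
        dishes=load_dishes(data_dir / FILE_NAMES["dishes"], data_dir / FILE_NAMES["recipes"]),
        composition=load_composition(data_dir / FILE_NAMES["composition"]),
        factors=load_factors(data_dir / FILE_NAMES["factors"], data_dir / FILE_NAMES["prices"]),
        guidelines=load_guidelines(data_dir / FILE_NAMES["guidelines"]),
        config=load_config(data_dir / FILE_NAMES["config"]),
    )
    validate_campaign(campaign)
    return campaign


def validate_campaign(campaign: Campaign) -> None:
    """Check that every cross-reference in the dataset resolves."""
    # menus -> dishes
    unknown_dishes = sorted(set(campaign.menus["dish_id"]) - set(campaign.dishes))
    if unknown_dishes:
        raise IntegrityError(f"menu references unknown dish ids: {unknown_dishes}")

    # recipes -> composition, factors, prices
    missing_comp: set[str] = set()
    missing_factor: set[str] = set()
    for dish in campaign.dishes.values():
        for item_id, _ in dish.recipe:
            if item_id not in campaign.composition:
                missing_comp.add(item_id)
            else:
                try:
                    campaign.factors.production_ef(item_id, dish.category)
                    campaign.factors.price(item_id, dish.category)
                    campaign.factors.transport_ef(item_id, dish.category)
                except IntegrityError:
                    missing_factor.add(item_id)
    if missing_comp:
        raise IntegrityError(
            f"recipe items missing from the composition table: {sorted(missing_comp)}"
        )
    if missing_factor:
        raise IntegrityError(
            f"recipe items with no resolvable factor/price: {sorted(missing_factor)}"
        )

    campaign.factors.disposal_ef(campaign.config.disposal_method)

    # observations -> config cases
    unknown_cases = sorted(set(campaign.observations["case_id"]) - set(campaign.config.case_ids))
    if unknown_cases:
        raise IntegrityError(f"observations reference undeclared cases: {unknown_cases}")

    # every observation cell must be backed by >= 1 menu dish of its category,
    # and every menu dish must have its category weighed that day
    menu_cats: set[tuple[str, str, str]] = set()
    for row in campaign.menus.itertuples(index=False):
        cat = campaign.dishes[row.dish_id].category.value
        menu_cats.add((row.date, row.school_id, cat))
    obs_cats = {
        (row.date, row.school_id, row.category)
        for row in campaign.observations.itertuples(index=False)
    }
    orphan_obs = sorted(obs_cats - menu_cats)
    if orphan_obs:
        raise IntegrityError(
            f"waste observations with no dish of that category on the menu: {orphan_obs}"
        )
    orphan_menu = sorted(menu_cats - obs_cats)
    if orphan_menu:
        raise IntegrityError(
            f"menu categories never weighed (missing observation rows): {orphan_menu}"
        )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_campaign(campaign: Campaign, out_dir: str | Path) -> list[Path]:
    """Write a campaign directory that :func:`load_campaign` reproduces exactly.

    Floats are serialised with Python's shortest round-tripping ``repr`` so the
    write-then-load cycle is bit-identical on every numeric field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / FILE_NAMES[name]
        frame.to_csv(path, index=False, encoding="utf-8")
        written.append(path)

    _write("observations", campaign.observations)
    _write("menus", campaign.menus)

    dish_rows, recipe_rows = [], []
    for dish in campaign.dishes.values():
        m1, m2, m3 = dish.serving_measurements_g
        dish_rows.append(
            {
                "dish_id": dish.dish_id,
                "name": dish.name,
                "category": dish.category.value,
                "serving1_g": repr(m1),
                "serving2_g": repr(m2),
                "serving3_g": repr(m3),
                "avg_serving_g": repr(dish.avg_serving_g),
            }
        )
        for item_id, grams in dish.recipe:
            recipe_rows.append(
                {"dish_id": dish.dish_id, "food_item_id": item_id,
                 "grams_per_serving": repr(grams)}
            )
    _write("dishes", pd.DataFrame(dish_rows))
    _write("recipes", pd.DataFrame(recipe_rows))

    comp_rows = [
        {"food_item_id": rec.food_item_id,
         **{k: repr(v) for k, v in rec.profile_per_100g.to_dict().items()}}
        for rec in campaign.composition.values()
    ]
    _write("composition", pd.DataFrame(comp_rows, columns=["food_item_id", *COMPONENTS]))

    factor_rows, price_rows = [], []
    for scope, row in campaign.factors.rows.items():
        if row.production_ef is not None or row.transport_ef is not None:
            factor_rows.append(
                {
                    "scope": scope,
                    "production_ef_kgco2e_per_kg": (
                        "" if row.production_ef is None else repr(row.production_ef)
                    ),
                    "transport_ef_kgco2e_per_kg_km": (
                        "" if row.transport_ef is None else repr(row.transport_ef)
                    ),
                    "disposal_ef_kgco2e_per_kg": "",
                }
            )
        if row.price is not None:
            price_rows.append({"scope": scope, "price_eur_per_kg": repr(row.price)})
    for method, ef in campaign.factors.disposal_factors.items():
        factor_rows.append(
            {
                "scope": f"disposal:{method}",
                "production_ef_kgco2e_per_kg": "",
                "transport_ef_kgco2e_per_kg_km": "",
                "disposal_ef_kgco2e_per_kg": repr(ef),
            }
        )
    _write("factors", pd.DataFrame(factor_rows))
    _write("prices", pd.DataFrame(price_rows))

    guideline_rows = [
        {
            "quantity": b.quantity,
            "lower": "" if b.lower is None else repr(b.lower),
            "upper": "" if b.upper is None else repr(b.upper),
            "units": b.units,
            "basis": b.basis,
        }
        for b in campaign.guidelines
    ]
    _write(
        "guidelines",
        pd.DataFrame(guideline_rows, columns=["quantity", "lower", "upper", "units", "basis"]),
    )

    config_payload = {
        "cases": [
            {
                "case_id": c.case_id,
                "transport_distance_km": c.transport_distance_km,
                "full_price_eur": c.full_price_eur,
                "procurement_budget_eur": c.procurement_budget_eur,
                "meals_served": c.meals_served,
            }
            for c in campaign.config.cases
        ],
        "disposal_method": campaign.config.disposal_method,
    }
    config_path = out_dir / FILE_NAMES["config"]
    config_path.write_text(yaml.safe_dump(config_payload, sort_keys=False), encoding="utf-8")
    written.append(config_path)
    return written


def write_report_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result table as ``<name>.csv`` (UTF-8, comma, '.' decimals).

    Empty frames (with columns) produce header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in tables.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False, encoding="utf-8")
        paths.append(path)
    return paths
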