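"""Synthetic two-case campaigns with planted, recoverable ground truth.

The generator emulates an aggregate-selective-weighing campaign: two
procurement cases, a handful of schools each, seven food categories, a dish
library with three weighed servings per dish, and day-to-day waste fractions
drawn from Beta distributions with planted means.  Everything downstream of
``observations.csv`` is deterministic given the spec and its seed.

The bundled composition, emission-factor, price and guideline tables are
internally consistent toy values for testing the pipeline; they are NOT the
confidential procurement inputs of any real catering service.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import (
    Campaign,
    CampaignConfig,
    CaseConfig,
    CompositionRecord,
    DishServing,
    FactorRow,
    FactorTable,
    FoodCategory,
    GuidelineBound,
    GuidelineBounds,
    CATEGORY_CODES,
    validate_campaign,
    write_campaign,
)
from .errors import ValidationError
from .nutrients import NutrientProfile

# ---------------------------------------------------------------------------
# bundled toy tables (illustrative values only)
# ---------------------------------------------------------------------------

#: per 100 g edible food; sparse (unlisted components are zero)
COMPOSITION_TABLE: dict[str, dict[str, float]] = {
    "pasta": {"energy_kcal": 150, "protein_g": 5, "carbohydrate_g": 30, "soluble_sugars_g": 1,
              "fat_g": 1, "fibre_g": 1.8, "vit_b1_mg": 0.05, "vit_b3_mg": 0.8, "vit_b9_ug": 8,
              "na_mg": 2, "k_mg": 40, "ca_mg": 10, "p_mg": 60, "fe_mg": 0.6, "zn_mg": 0.8,
              "cu_mg": 0.1},
    "rice": {"energy_kcal": 140, "protein_g": 3, "carbohydrate_g": 31, "soluble_sugars_g": 0.2,
             "fat_g": 0.4, "fibre_g": 0.9, "vit_b1_mg": 0.03, "vit_b3_mg": 1.0, "vit_b9_ug": 4,
             "k_mg": 30, "ca_mg": 5, "p_mg": 45, "fe_mg": 0.4, "zn_mg": 0.7, "cu_mg": 0.1},
    "potato_gnocchi": {"energy_kcal": 130, "protein_g": 3.5, "carbohydrate_g": 28,
                       "soluble_sugars_g": 1.2, "fat_g": 0.5, "fibre_g": 1.5, "vit_c_mg": 4,
                       "k_mg": 180, "ca_mg": 12, "p_mg": 55, "fe_mg": 0.7, "zn_mg": 0.5,
                       "cu_mg": 0.1, "vit_b9_ug": 10},
    "tomato_sauce": {"energy_kcal": 30, "protein_g": 1.2, "carbohydrate_g": 5,
                     "soluble_sugars_g": 4, "fat_g": 0.3, "fibre_g": 1.5, "vit_a_ug": 45,
                     "vit_c_mg": 14, "vit_b9_ug": 20, "k_mg": 250, "ca_mg": 12, "p_mg": 25,
                     "fe_mg": 0.4, "na_mg": 10, "zn_mg": 0.2, "cu_mg": 0.1},
    "olive_oil": {"energy_kcal": 900, "fat_g": 100, "vit_a_ug": 36, "vit_d_ug": 0},
    "bread_white": {"energy_kcal": 270, "protein_g": 9, "carbohydrate_g": 55,
                    "soluble_sugars_g": 2, "fat_g": 2, "fibre_g": 3.2, "vit_b1_mg": 0.1,
                    "vit_b2_mg": 0.05, "vit_b3_mg": 1.3, "vit_b9_ug": 25, "na_mg": 500,
                    "k_mg": 120, "ca_mg": 25, "p_mg": 90, "fe_mg": 1.0, "zn_mg": 0.9,
                    "cu_mg": 0.2},
    "beef": {"energy_kcal": 190, "protein_g": 26, "fat_g": 9, "cholesterol_mg": 70,
             "vit_b1_mg": 0.08, "vit_b2_mg": 0.18, "vit_b3_mg": 5.0, "vit_b6_mg": 0.4,
             "vit_b12_ug": 2.0, "na_mg": 60, "k_mg": 330, "ca_mg": 6, "p_mg": 200,
             "fe_mg": 2.1, "zn_mg": 4.2, "cu_mg": 0.1},
    "chicken": {"energy_kcal": 150, "protein_g": 27, "fat_g": 4, "cholesterol_mg": 75,
                "vit_b3_mg": 9.0, "vit_b6_mg": 0.5, "vit_b12_ug": 0.4, "na_mg": 70,
                "k_mg": 300, "ca_mg": 8, "p_mg": 210, "fe_mg": 0.9, "zn_mg": 1.5,
                "cu_mg": 0.1},
    "codfish": {"energy_kcal": 90, "protein_g": 20, "fat_g": 0.8, "cholesterol_mg": 45,
                "vit_b3_mg": 2.0, "vit_b6_mg": 0.25, "vit_b12_ug": 1.0, "vit_d_ug": 1.5,
                "na_mg": 90, "k_mg": 380, "ca_mg": 15, "p_mg": 190, "fe_mg": 0.4,
                "zn_mg": 0.5, "cu_mg": 0.05},
    "cheese_fresh": {"energy_kcal": 300, "protein_g": 19, "fat_g": 24,
                     "cholesterol_mg": 90, "soluble_sugars_g": 1.5, "carbohydrate_g": 1.5,
                     "vit_a_ug": 250, "vit_b2_mg": 0.3, "vit_b12_ug": 1.5, "vit_d_ug": 0.4,
                     "na_mg": 450, "k_mg": 100, "ca_mg": 600, "p_mg": 380, "fe_mg": 0.2,
                     "zn_mg": 2.8, "cu_mg": 0.05},
    "lentils": {"energy_kcal": 110, "protein_g": 8, "carbohydrate_g": 17,
                "soluble_sugars_g": 0.6, "fat_g": 0.5, "fibre_g": 8, "vit_b1_mg": 0.15,
                "vit_b9_ug": 90, "na_mg": 4, "k_mg": 330, "ca_mg": 25, "p_mg": 150,
                "fe_mg": 3.3, "zn_mg": 1.3, "cu_mg": 0.3},
    "egg": {"energy_kcal": 140, "protein_g": 12.5, "fat_g": 9.5, "cholesterol_mg": 370,
            "vit_a_ug": 160, "vit_b2_mg": 0.4, "vit_b12_ug": 1.1, "vit_d_ug": 1.8,
            "na_mg": 140, "k_mg": 130, "ca_mg": 50, "p_mg": 200, "fe_mg": 1.8,
            "zn_mg": 1.3, "cu_mg": 0.06},
    "carrot": {"energy_kcal": 35, "protein_g": 1, "carbohydrate_g": 7,
               "soluble_sugars_g": 5, "fat_g": 0.2, "fibre_g": 3, "vit_a_ug": 835,
               "vit_c_mg": 6, "vit_b9_ug": 19, "na_mg": 70, "k_mg": 320, "ca_mg": 33,
               "p_mg": 35, "fe_mg": 0.3, "zn_mg": 0.2, "cu_mg": 0.05},
    "zucchini": {"energy_kcal": 17, "protein_g": 1.2, "carbohydrate_g": 3,
                 "soluble_sugars_g": 2.5, "fat_g": 0.3, "fibre_g": 1, "vit_a_ug": 10,
                 "vit_c_mg": 18, "vit_b9_ug": 24, "k_mg": 260, "ca_mg": 16, "p_mg": 38,
                 "fe_mg": 0.4, "zn_mg": 0.3, "cu_mg": 0.05},
    "green_beans": {"energy_kcal": 31, "protein_g": 1.8, "carbohydrate_g": 7,
                    "soluble_sugars_g": 3.3, "fat_g": 0.2, "fibre_g": 2.7, "vit_a_ug": 35,
                    "vit_c_mg": 12, "vit_b9_ug": 33, "k_mg": 211, "ca_mg": 37, "p_mg": 38,
                    "fe_mg": 1.0, "zn_mg": 0.2, "cu_mg": 0.07},
    "apple": {"energy_kcal": 52, "carbohydrate_g": 14, "soluble_sugars_g": 10,
              "fibre_g": 2.4, "vit_c_mg": 5, "vit_b9_ug": 3, "k_mg": 107, "ca_mg": 6,
              "p_mg": 11, "fe_mg": 0.1, "zn_mg": 0.04, "cu_mg": 0.03},
    "pear": {"energy_kcal": 57, "carbohydrate_g": 15, "soluble_sugars_g": 10,
             "fibre_g": 3.1, "vit_c_mg": 4, "vit_b9_ug": 7, "k_mg": 116, "ca_mg": 9,
             "p_mg": 12, "fe_mg": 0.2, "zn_mg": 0.1, "cu_mg": 0.08},
    "orange": {"energy_kcal": 47, "carbohydrate_g": 12, "soluble_sugars_g": 9,
               "fibre_g": 2.4, "vit_c_mg": 53, "vit_a_ug": 11, "vit_b9_ug": 30,
               "k_mg": 181, "ca_mg": 40, "p_mg": 14, "fe_mg": 0.1, "zn_mg": 0.07,
               "cu_mg": 0.05},
    "cake": {"energy_kcal": 380, "protein_g": 5, "carbohydrate_g": 55,
             "soluble_sugars_g": 30, "fat_g": 15, "cholesterol_mg": 60, "fibre_g": 1.2,
             "vit_a_ug": 80, "vit_b2_mg": 0.1, "na_mg": 300, "k_mg": 110, "ca_mg": 60,
             "p_mg": 120, "fe_mg": 1.0, "zn_mg": 0.5, "cu_mg": 0.05},
}

#: dish templates: category -> [(name, recipe grams per serving)]
DISH_TEMPLATES: dict[str, list[tuple[str, dict[str, float]]]] = {
    "starchy": [
        ("pasta_tomato", {"pasta": 90, "tomato_sauce": 25, "olive_oil": 5}),
        ("rice_oil", {"rice": 95, "olive_oil": 5}),
        ("gnocchi_tomato", {"potato_gnocchi": 90, "tomato_sauce": 30, "olive_oil": 4}),
    ],
    "bread": [("bread_roll", {"bread_white": 50})],
    "protein": [
        ("roast_beef", {"beef": 80, "olive_oil": 5}),
        ("chicken_breast", {"chicken": 85, "olive_oil": 5}),
        ("baked_codfish", {"codfish": 85, "olive_oil": 5}),
        ("fresh_cheese_plate", {"cheese_fresh": 70}),
        ("lentil_stew", {"lentils": 80, "tomato_sauce": 20, "olive_oil": 4}),
        ("omelette", {"egg": 75, "olive_oil": 5}),
    ],
    "vegetable": [
        ("steamed_carrots", {"carrot": 75, "olive_oil": 5}),
        ("zucchini_saute", {"zucchini": 75, "olive_oil": 5}),
        ("green_beans_oil", {"green_beans": 75, "olive_oil": 5}),
    ],
    "fruit": [
        ("apple_fruit", {"apple": 100}),
        ("pear_fruit", {"pear": 100}),
        ("orange_fruit", {"orange": 100}),
    ],
    "dessert": [("sponge_cake", {"cake": 80})],
    "other": [
        ("pizza_margherita", {"bread_white": 80, "tomato_sauce": 40, "cheese_fresh": 35}),
    ],
}

#: production emission factors, kg CO2e per kg (item overrides, category fallback)
PRODUCTION_EF_ITEMS: dict[str, float] = {
    "beef": 12.0, "chicken": 4.5, "codfish": 5.2, "cheese_fresh": 8.5,
    "lentils": 1.4, "egg": 3.5, "olive_oil": 5.5,
}
PRODUCTION_EF_CATEGORIES: dict[str, float] = {
    "starchy": 1.6, "bread": 1.1, "protein": 4.5, "vegetable": 0.45,
    "fruit": 0.40, "dessert": 2.2, "other": 2.0,
}
#: kg CO2e per kg per km, uniform across categories (small-van cold chain)
TRANSPORT_EF_PER_KG_KM = 0.003
DISPOSAL_EF: dict[str, float] = {"composting": 0.05, "landfill": 0.7, "incineration": 0.2}

PRICE_ITEMS: dict[str, float] = {
    "pasta": 1.6, "rice": 2.2, "potato_gnocchi": 2.5, "tomato_sauce": 1.8,
    "olive_oil": 8.0, "bread_white": 3.2, "beef": 11.0, "chicken": 7.5,
    "codfish": 12.0, "cheese_fresh": 9.0, "lentils": 2.4, "egg": 3.0,
    "carrot": 1.2, "zucchini": 1.8, "green_beans": 2.2, "apple": 1.8,
    "pear": 2.0, "orange": 1.7, "cake": 6.5,
}
PRICE_CATEGORIES: dict[str, float] = {
    "starchy": 2.0, "bread": 3.2, "protein": 8.0, "vegetable": 1.7,
    "fruit": 1.8, "dessert": 6.5, "other": 4.5,
}

#: illustrative school-lunch bounds (placeholder set, clearly not normative)
GUIDELINE_ROWS: tuple[tuple[str, Optional[float], Optional[float]], ...] = (
    ("energy_kcal", 550.0, 850.0),
    ("protein_g", 12.0, 40.0),
    ("fat_g", 15.0, 35.0),
    ("carbohydrate_g", 60.0, 130.0),
    ("fibre_g", 4.0, None),
    ("vit_c_mg", 10.0, None),
    ("ca_mg", 100.0, None),
    ("fe_mg", 2.0, None),
    ("na_mg", None, 1200.0),
    ("protein_energy_pct", 10.0, 20.0),
    ("fat_energy_pct", 20.0, 38.0),
    ("carbohydrate_energy_pct", 45.0, 65.0),
)


def default_composition() -> dict[str, CompositionRecord]:
    return {
        item: CompositionRecord(item, NutrientProfile.from_mapping(values))
        for item, values in COMPOSITION_TABLE.items()
    }


def default_factors() -> FactorTable:
    rows: dict[str, FactorRow] = {}
    for item, ef in PRODUCTION_EF_ITEMS.items():
        rows[item] = FactorRow(production_ef=ef, price=PRICE_ITEMS.get(item))
    for item, price in PRICE_ITEMS.items():
        if item not in rows:
            rows[item] = FactorRow(price=price)
    for code in CATEGORY_CODES:
        rows[code] = FactorRow(
            production_ef=PRODUCTION_EF_CATEGORIES[code],
            transport_ef=TRANSPORT_EF_PER_KG_KM,
            price=PRICE_CATEGORIES[code],
        )
    return FactorTable(rows, DISPOSAL_EF)


def default_guidelines() -> GuidelineBounds:
    bounds = []
    for quantity, lower, upper in GUIDELINE_ROWS:
        units = "pct" if quantity.endswith("_pct") else quantity.rsplit("_", 1)[1]
        bounds.append(GuidelineBound(quantity, lower, upper, units, "both"))
    return GuidelineBounds(bounds)


# ---------------------------------------------------------------------------
# campaign specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryParams:
    """Planted behaviour of one food category in one case."""

    mean_waste_fraction: float
    concentration: float  # Beta concentration; math.inf = deterministic fraction
    serving_mean_g: float
    serving_sd_g: float


@dataclass(frozen=True)
class CaseSpec:
    case_id: str
    n_days: int
    n_schools: int
    children_range: tuple[int, int]
    category_params: dict[str, CategoryParams]
    other_prob: float = 0.0  # P(an 'other' dish replaces starchy + protein)
    dessert_prob: float = 0.0  # P(dessert replaces fruit)
    transport_distance_km: float = 10.0
    full_price_eur: Optional[float] = None
    procurement_budget_eur: Optional[float] = None


@dataclass(frozen=True)
class CampaignSpec:
    seed: int
    cases: tuple[CaseSpec, ...]
    disposal_method: str = "composting"


def validate_spec(spec: CampaignSpec) -> None:
    if not spec.cases:
        raise ValidationError("spec must define at least one case")
    for case in spec.cases:
        if case.n_days < 1 or case.n_schools < 1:
            raise ValidationError(f"{case.case_id}: n_days and n_schools must be >= 1")
        lo, hi = case.children_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"{case.case_id}: bad children range {case.children_range}")
        for code, params in case.category_params.items():
            if code not in CATEGORY_CODES:
                raise ValidationError(f"{case.case_id}: unknown category {code!r}")
            if not 0.0 <= params.mean_waste_fraction <= 1.0:
                raise ValidationError(
                    f"{case.case_id}/{code}: waste fraction must lie in [0, 1]"
                )
            if not (params.concentration > 0):
                raise ValidationError(f"{case.case_id}/{code}: concentration must be > 0")
            if params.serving_mean_g <= 0:
                raise ValidationError(f"{case.case_id}/{code}: serving mean must be > 0")
            if params.serving_sd_g < 0 or params.serving_sd_g >= params.serving_mean_g / 2:
                raise ValidationError(
                    f"{case.case_id}/{code}: serving SD must satisfy 0 <= sd < mean/2"
                )
        missing = set(CATEGORY_CODES) - set(case.category_params)
        if missing:
            raise ValidationError(f"{case.case_id}: missing category params for {sorted(missing)}")
        for name, p in (("other_prob", case.other_prob), ("dessert_prob", case.dessert_prob)):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{case.case_id}: {name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_fraction(rng: np.random.Generator, params: CategoryParams) -> float:
    mean, conc = params.mean_waste_fraction, params.concentration
    if mean == 0.0 or mean == 1.0 or math.isinf(conc):
        return mean
    return float(rng.beta(mean * conc, (1.0 - mean) * conc))


def _draw_servings(rng: np.random.Generator, params: CategoryParams) -> tuple[float, float, float]:
    if params.serving_sd_g == 0:
        return (params.serving_mean_g,) * 3
    for _ in range(100):
        draws = rng.normal(params.serving_mean_g, params.serving_sd_g, size=3)
        if np.all(draws > 0):
            return tuple(float(d) for d in draws)
    raise ValidationError("could not draw positive serving measurements")


def generate_campaign(spec: CampaignSpec) -> tuple[Campaign, dict]:
    """Generate a full in-memory campaign plus its ground-truth record.

    Deterministic under a fixed spec (including its seed).  The ground truth
    carries the planted category fractions and the analytically expected
    waste masses, costs and production emissions, computed by direct
    summation from the planted parameters and the realised menus.
    """
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    composition = default_composition()
    factors = default_factors()
    guidelines = default_guidelines()

    dishes: dict[str, DishServing] = {}
    for case in spec.cases:
        for code, templates in DISH_TEMPLATES.items():
            params = case.category_params[code]
            for name, recipe in templates:
                measurements = _draw_servings(rng, params)
                dishes[f"{case.case_id}_{name}"] = DishServing(
                    dish_id=f"{case.case_id}_{name}",
                    name=name.replace("_", " "),
                    category=FoodCategory(code),
                    serving_measurements_g=measurements,
                    avg_serving_g=sum(measurements) / 3.0,
                    recipe=tuple(recipe.items()),
                )

    start = _dt.date(2023, 1, 9)
    obs_rows: list[dict] = []
    menu_rows: list[dict] = []
    truth_cases: dict[str, dict] = {}

    for case in spec.cases:
        expected_waste_g = {code: 0.0 for code in CATEGORY_CODES}
        served_g_by_cat = {code: 0.0 for code in CATEGORY_CODES}
        item_served_g: dict[tuple[str, str], float] = {}
        for day in range(case.n_days):
            date = (start + _dt.timedelta(days=day)).isoformat()
            season = "winter" if day < case.n_days // 2 else "spring"
            serve_other = rng.random() < case.other_prob
            serve_dessert = rng.random() < case.dessert_prob
            categories = ["bread", "vegetable"]
            categories.append("dessert" if serve_dessert else "fruit")
            if serve_other:
                categories.append("other")
            else:
                categories.extend(["starchy", "protein"])
            day_dishes = {
                code: f"{case.case_id}_{DISH_TEMPLATES[code][int(rng.integers(len(DISH_TEMPLATES[code])))][0]}"
                for code in sorted(categories)
            }
            for school in range(case.n_schools):
                school_id = f"{case.case_id}_s{school + 1}"
                children = int(rng.integers(case.children_range[0], case.children_range[1] + 1))
                for code in sorted(categories):
                    dish = dishes[day_dishes[code]]
                    menu_rows.append(
                        {"date": date, "school_id": school_id, "dish_id": dish.dish_id}
                    )
                    served = dish.avg_serving_g * children
                    fraction = _draw_fraction(rng, case.category_params[code])
                    obs_rows.append(
                        {
                            "date": date,
                            "school_id": school_id,
                            "case_id": case.case_id,
                            "category": code,
                            "waste_mass_g": fraction * served,
                            "children_served": children,
                            "season": season,
                        }
                    )
                    served_g_by_cat[code] += served
                    expected_waste_g[code] += case.category_params[code].mean_waste_fraction * served
                    recipe_total = sum(g for _, g in dish.recipe)
                    for item_id, grams in dish.recipe:
                        key = (code, item_id)
                        item_served_g[key] = (
                            item_served_g.get(key, 0.0) + grams / recipe_total * served
                        )

        # analytic expectations from planted fractions and the realised menus
        expected_cost = 0.0
        expected_production = 0.0
        for code in CATEGORY_CODES:
            if served_g_by_cat[code] <= 0:
                continue
            mean_frac = case.category_params[code].mean_waste_fraction
            cat_items = {k[1]: v for k, v in item_served_g.items() if k[0] == code}
            total_item_g = sum(cat_items.values())
            for item_id, grams in cat_items.items():
                item_waste_kg = mean_frac * grams / 1000.0
                expected_cost += item_waste_kg * factors.price(item_id, FoodCategory(code))
                expected_production += item_waste_kg * factors.production_ef(
                    item_id, FoodCategory(code)
                )
            assert abs(total_item_g - served_g_by_cat[code]) < 1e-6 * max(total_item_g, 1.0)

        total_served = sum(served_g_by_cat.values())
        total_expected_waste = sum(expected_waste_g.values())
        truth_cases[case.case_id] = {
            "planted_waste_fractions": {
                code: case.category_params[code].mean_waste_fraction
                for code in CATEGORY_CODES
            },
            "served_kg_by_category": {
                code: served_g_by_cat[code] / 1000.0 for code in CATEGORY_CODES
            },
            "expected_waste_kg_by_category": {
                code: expected_waste_g[code] / 1000.0 for code in CATEGORY_CODES
            },
            "expected_total_waste_kg": total_expected_waste / 1000.0,
            "expected_total_waste_pct": (
                100.0 * total_expected_waste / total_served if total_served else 0.0
            ),
            "expected_waste_cost_eur": expected_cost,
            "expected_waste_production_kgco2e": expected_production,
            "n_days": case.n_days,
        }

    config = CampaignConfig(
        cases=tuple(
            CaseConfig(
                case_id=case.case_id,
                transport_distance_km=case.transport_distance_km,
                full_price_eur=case.full_price_eur,
                procurement_budget_eur=case.procurement_budget_eur,
            )
            for case in spec.cases
        ),
        disposal_method=spec.disposal_method,
    )
    campaign = Campaign(
        observations=pd.DataFrame(obs_rows),
        menus=pd.DataFrame(menu_rows),
        dishes=dishes,
        composition=composition,
        factors=factors,
        guidelines=guidelines,
        config=config,
    )
    validate_campaign(campaign)
    ground_truth = {"seed": spec.seed, "cases": truth_cases}
    return campaign, ground_truth


def write_generated(campaign: Campaign, ground_truth: dict, out_dir: str | Path) -> list[Path]:
    """Write the campaign directory plus ``ground_truth.json``."""
    out_dir = Path(out_dir)
    paths = write_campaign(campaign, out_dir)
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(ground_truth, indent=2, sort_keys=True), encoding="utf-8")
    paths.append(truth_path)
    return paths


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _params(fractions: Mapping[str, float], concentration: float) -> dict[str, CategoryParams]:
    servings = {
        "starchy": (120.0, 8.0), "bread": (50.0, 3.0), "protein": (90.0, 6.0),
        "vegetable": (80.0, 6.0), "fruit": (100.0, 7.0), "dessert": (80.0, 5.0),
        "other": (150.0, 10.0),
    }
    return {
        code: CategoryParams(
            mean_waste_fraction=fractions[code],
            concentration=concentration,
            serving_mean_g=servings[code][0],
            serving_sd_g=servings[code][1],
        )
        for code in CATEGORY_CODES
    }


def paperlike_preset(seed: int = 1, n_days: tuple[int, int] = (20, 19)) -> CampaignSpec:
    """Two-case spec mimicking the reported campaign scale.

    Case A (local-organic-like, 20 collection days) plants ~24 % expected
    total waste; case B (organic-like, 19 days) plants ~42 %, with fruit and
    vegetable fractions above 50 %.
    """
    case_a = CaseSpec(
        case_id="LOC-ORG",
        n_days=n_days[0],
        n_schools=2,
        children_range=(70, 130),
        category_params=_params(
            {"starchy": 0.16, "bread": 0.28, "protein": 0.10, "vegetable": 0.42,
             "fruit": 0.30, "dessert": 0.15, "other": 0.10},
            concentration=20.0,
        ),
        other_prob=0.10,
        dessert_prob=0.05,
        transport_distance_km=10.0,
        full_price_eur=6.0,
        procurement_budget_eur=5000.0,
    )
    case_b = CaseSpec(
        case_id="ORG",
        n_days=n_days[1],
        n_schools=2,
        children_range=(70, 130),
        category_params=_params(
            {"starchy": 0.35, "bread": 0.45, "protein": 0.25, "vegetable": 0.55,
             "fruit": 0.55, "dessert": 0.30, "other": 0.12},
            concentration=20.0,
        ),
        other_prob=0.15,
        dessert_prob=0.20,
        transport_distance_km=25.0,
        full_price_eur=5.0,
        procurement_budget_eur=4500.0,
    )
    return CampaignSpec(seed=seed, cases=(case_a, case_b))
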