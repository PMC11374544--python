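"""Greenhouse-gas emissions embodied in plate waste.

Three components per food category: production (item mass x production EF),
transport (item mass x per-km EF x central-kitchen-to-school distance) and
disposal (mass x disposal-method EF).  Category waste is decomposed across
recipe items proportionally to the served item mix, so item-level factors can
be mixed freely with category-level fallbacks.

The share of the supplied-food footprint attributed to waste uses the
*production* emissions of the waste in the numerator and the production
emissions of all supplied food in the denominator; an all-components variant
is reported alongside under a distinct name.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .data_io import Campaign, FactorTable, FoodCategory, CATEGORY_CODES, as_category
from .errors import UndefinedRatioError, ValidationError
from .waste_accounting import CategoryDayAccount, decompose_waste_to_items


def production_emissions(
    masses_kg: Mapping[str, float], factors: FactorTable, category: FoodCategory
) -> float:
    """kg CO2e from producing the given item masses (item EF, else category EF)."""
    return sum(
        mass * factors.production_ef(item_id, category)
        for item_id, mass in masses_kg.items()
    )


def transport_and_disposal_emissions(
    masses_kg: Mapping[str, float],
    factors: FactorTable,
    category: FoodCategory,
    distance_km: float,
    disposal_method: str,
) -> tuple[float, float]:
    """(transport, disposal) kg CO2e for the given item masses."""
    if distance_km < 0:
        raise ValidationError("transport distance must be >= 0")
    transport = sum(
        mass * factors.transport_ef(item_id, category) * distance_km
        for item_id, mass in masses_kg.items()
    )
    disposal_ef = factors.disposal_ef(disposal_method)
    disposal = sum(masses_kg.values()) * disposal_ef
    return transport, disposal


def per_serving_factor(total_kgco2e: float, servings_count: float) -> float:
    """Average kg CO2e per serving."""
    if servings_count < 1:
        raise UndefinedRatioError("servings count must be >= 1")
    return total_kgco2e / servings_count


def waste_share_of_supply(waste_kgco2e: float, supplied_total_kgco2e: float) -> float:
    """Waste emissions as a percent of the supplied-food footprint."""
    if supplied_total_kgco2e <= 0:
        raise UndefinedRatioError("supplied-food footprint must be > 0")
    return 100.0 * waste_kgco2e / supplied_total_kgco2e


@dataclass(frozen=True)
class CategoryEmissions:
    category: FoodCategory
    waste_kg: float
    production_kgco2e: float
    transport_kgco2e: float
    disposal_kgco2e: float
    servings_count: float  # divisor used for the per-serving factor

    @property
    def total_kgco2e(self) -> float:
        return self.production_kgco2e + self.transport_kgco2e + self.disposal_kgco2e

    @property
    def ef_per_kg_waste(self) -> float:
        if self.waste_kg <= 0:
            return 0.0
        return self.total_kgco2e / self.waste_kg

    @property
    def ef_per_serving(self) -> float:
        if self.servings_count < 1:
            return 0.0
        return self.total_kgco2e / self.servings_count


@dataclass
class EmissionAccount:
    """Case-level waste footprint with component, per-kg and per-serving views."""

    case_id: str
    per_category: dict[str, CategoryEmissions]
    supplied_production_kgco2e: float
    meals: int

    @property
    def production_kgco2e(self) -> float:
        return sum(c.production_kgco2e for c in self.per_category.values())

    @property
    def transport_kgco2e(self) -> float:
        return sum(c.transport_kgco2e for c in self.per_category.values())

    @property
    def disposal_kgco2e(self) -> float:
        return sum(c.disposal_kgco2e for c in self.per_category.values())

    @property
    def total_kgco2e(self) -> float:
        return self.production_kgco2e + self.transport_kgco2e + self.disposal_kgco2e

    @property
    def waste_share_of_supply_pct(self) -> float:
        """Production emissions of waste over the supplied-food footprint."""
        return waste_share_of_supply(self.production_kgco2e, self.supplied_production_kgco2e)

    @property
    def waste_share_all_components_pct(self) -> float:
        """All three waste components over the supplied-food footprint."""
        return waste_share_of_supply(self.total_kgco2e, self.supplied_production_kgco2e)

    @property
    def per_meal_production_kgco2e(self) -> float:
        return self.production_kgco2e / self.meals

    @property
    def per_meal_total_kgco2e(self) -> float:
        return self.total_kgco2e / self.meals


def _servings_by_category(
    campaign: Campaign, accounts: Sequence[CategoryDayAccount], case_id: str
) -> dict[str, float]:
    """Number of servings distributed per category over the campaign.

    One serving = one child served the category on one day.  The starchy
    divisor is the mean of the starchy and bread serving counts (starchy
    dishes and bread are two courses of the same staple, counted once)."""
    counts: dict[str, float] = {}
    for a in accounts:
        if a.case_id != case_id:
            continue
        counts[a.category.value] = counts.get(a.category.value, 0.0) + float(a.children)
    starchy = counts.get(FoodCategory.STARCHY.value)
    bread = counts.get(FoodCategory.BREAD.value)
    if starchy is not None and bread is not None:
        counts[FoodCategory.STARCHY.value] = (starchy + bread) / 2.0
    return counts


def case_emissions(
    campaign: Campaign, accounts: Sequence[CategoryDayAccount], case_id: str
) -> EmissionAccount:
    """Full waste-emission account for one case."""
    case_cfg = campaign.config.case(case_id)
    distance = case_cfg.transport_distance_km
    method = campaign.config.disposal_method
    allocation = decompose_waste_to_items(campaign, accounts, case_id)
    servings = _servings_by_category(campaign, accounts, case_id)

    per_category: dict[str, CategoryEmissions] = {}
    supplied_production = 0.0
    for code in CATEGORY_CODES:
        subset = allocation[allocation["category"] == code]
        if subset.empty:
            continue
        category = as_category(code)
        waste_masses = dict(zip(subset["food_item_id"], subset["waste_kg"]))
        served_masses = dict(zip(subset["food_item_id"], subset["served_kg"]))
        production = production_emissions(waste_masses, campaign.factors, category)
        transport, disposal = transport_and_disposal_emissions(
            waste_masses, campaign.factors, category, distance, method
        )
        supplied_production += production_emissions(served_masses, campaign.factors, category)
        per_category[code] = CategoryEmissions(
            category=category,
            waste_kg=float(subset["waste_kg"].sum()),
            production_kgco2e=production,
            transport_kgco2e=transport,
            disposal_kgco2e=disposal,
            servings_count=servings.get(code, 0.0),
        )

    meals = case_cfg.meals_served
    if meals is None:
        case_accounts = [a for a in accounts if a.case_id == case_id]
        by_date: dict[str, int] = {}
        for a in case_accounts:
            by_date[a.date] = max(by_date.get(a.date, 0), a.children)
        meals = sum(by_date.values())
    return EmissionAccount(
        case_id=case_id,
        per_category=per_category,
        supplied_production_kgco2e=supplied_production,
        meals=int(meals),
    )


def emissions_table(accounts: Sequence[EmissionAccount]) -> pd.DataFrame:
    """Component/total/per-kg/per-serving table, one row per category plus a
    total row per case."""
    rows = []
    for account in accounts:
        for code in CATEGORY_CODES:
            cat = account.per_category.get(code)
            if cat is None:
                continue
            rows.append(
                {
                    "case_id": account.case_id,
                    "category": code,
                    "waste_kg": cat.waste_kg,
                    "production_kgco2e": cat.production_kgco2e,
                    "transport_kgco2e": cat.transport_kgco2e,
                    "disposal_kgco2e": cat.disposal_kgco2e,
                    "total_kgco2e": cat.total_kgco2e,
                    "ef_per_kg_waste": cat.ef_per_kg_waste,
                    "ef_per_serving": cat.ef_per_serving,
                }
            )
        waste_kg = sum(c.waste_kg for c in account.per_category.values())
        rows.append(
            {
                "case_id": account.case_id,
                "category": "total",
                "waste_kg": waste_kg,
                "production_kgco2e": account.production_kgco2e,
                "transport_kgco2e": account.transport_kgco2e,
                "disposal_kgco2e": account.disposal_kgco2e,
                "total_kgco2e": account.total_kgco2e,
                "ef_per_kg_waste": (
                    account.total_kgco2e / waste_kg if waste_kg > 0 else 0.0
                ),
                "ef_per_serving": account.per_meal_total_kgco2e,
            }
        )
    return pd.DataFrame(rows)
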