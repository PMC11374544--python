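"""Economic cost of plate waste via proportional budget allocation.

Each category gets a volume-weighted mean price over the items served in it;
category waste cost is waste mass times that price.  Because waste is
decomposed across items proportionally to the served mix, the category sum
equals the item-level cost sum exactly.  Amounts are carried at full
precision; rounding happens only in report emitters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .data_io import Campaign, FactorTable, FoodCategory, CATEGORY_CODES, as_category
from .errors import UndefinedRatioError, ValidationError
from .waste_accounting import CategoryDayAccount, decompose_waste_to_items


def category_cost_per_kg(
    procured_items: Sequence[tuple[str, float]],
    factors: FactorTable,
    category: FoodCategory,
) -> float:
    """Volume-weighted mean price (EUR/kg) of the items procured in a category.

    ``procured_items`` is a list of (food_item_id, mass_kg); prices resolve
    item-first with category fallback.
    """
    total_mass = sum(mass for _, mass in procured_items)
    if total_mass <= 0:
        raise UndefinedRatioError("category procured mass must be > 0")
    total_cost = sum(
        mass * factors.price(item_id, category) for item_id, mass in procured_items
    )
    return total_cost / total_mass


def waste_cost(category_waste_kg: float, cost_per_kg: float) -> float:
    """EUR lost in one category's waste."""
    if category_waste_kg < 0 or cost_per_kg < 0:
        raise ValidationError("waste mass and cost per kg must be >= 0")
    return category_waste_kg * cost_per_kg


def derived_cost_metrics(
    total_cost_eur: float,
    total_waste_kg: float,
    days: int,
    meals: Optional[int] = None,
    full_price_eur: Optional[float] = None,
    procurement_budget_eur: Optional[float] = None,
) -> dict[str, Optional[float]]:
    """Daily / per-kg / per-meal / share metrics from a case's cost total.

    Metrics whose denominator is not configured come back as ``None``
    (graceful degradation); zero denominators that *are* supplied raise.
    """
    if days < 1:
        raise UndefinedRatioError("collection days must be >= 1")
    if total_waste_kg < 0:
        raise UndefinedRatioError("total waste mass must be >= 0")
    out: dict[str, Optional[float]] = {
        "daily_cost_eur": total_cost_eur / days,
        # undefined (not zero) on a zero-waste campaign
        "cost_per_kg_eur": (
            total_cost_eur / total_waste_kg if total_waste_kg > 0 else None
        ),
        "cost_per_meal_eur": None,
        "share_of_full_price_pct": None,
        "share_of_procurement_budget_pct": None,
    }
    if meals is not None:
        if meals < 1:
            raise UndefinedRatioError("meals must be >= 1")
        out["cost_per_meal_eur"] = total_cost_eur / meals
        if full_price_eur is not None:
            if full_price_eur <= 0:
                raise UndefinedRatioError("full price must be > 0")
            out["share_of_full_price_pct"] = 100.0 * out["cost_per_meal_eur"] / full_price_eur
    if procurement_budget_eur is not None:
        if procurement_budget_eur <= 0:
            raise UndefinedRatioError("procurement budget must be > 0")
        out["share_of_procurement_budget_pct"] = 100.0 * total_cost_eur / procurement_budget_eur
    return out


@dataclass(frozen=True)
class CategoryCost:
    category: FoodCategory
    waste_kg: float
    cost_per_kg_eur: float
    waste_cost_eur: float
    servings_count: float

    @property
    def cost_per_serving_eur(self) -> float:
        if self.servings_count < 1:
            return 0.0
        return self.waste_cost_eur / self.servings_count


@dataclass
class CostAccount:
    """Case-level waste cost with per-category breakdown and derived metrics."""

    case_id: str
    per_category: dict[str, CategoryCost]
    days: int
    meals: Optional[int]
    full_price_eur: Optional[float]
    procurement_budget_eur: Optional[float]

    @property
    def total_cost_eur(self) -> float:
        return sum(c.waste_cost_eur for c in self.per_category.values())

    @property
    def total_waste_kg(self) -> float:
        return sum(c.waste_kg for c in self.per_category.values())

    @property
    def metrics(self) -> dict[str, Optional[float]]:
        return derived_cost_metrics(
            self.total_cost_eur,
            self.total_waste_kg,
            self.days,
            self.meals,
            self.full_price_eur,
            self.procurement_budget_eur,
        )


def case_costs(
    campaign: Campaign, accounts: Sequence[CategoryDayAccount], case_id: str
) -> CostAccount:
    """Full waste-cost account for one case."""
    from .carbon_footprint import _servings_by_category  # same serving convention

    allocation = decompose_waste_to_items(campaign, accounts, case_id)
    servings = _servings_by_category(campaign, accounts, case_id)
    per_category: dict[str, CategoryCost] = {}
    for code in CATEGORY_CODES:
        subset = allocation[allocation["category"] == code]
        if subset.empty:
            continue
        category = as_category(code)
        waste_kg = float(subset["waste_kg"].sum())
        # item-level sum == waste mass x the day-level served-mix mean price,
        # so the weighted-mean-price route and the item route agree exactly
        cost = sum(
            waste_cost(mass, campaign.factors.price(item_id, category))
            for item_id, mass in zip(subset["food_item_id"], subset["waste_kg"])
        )
        if waste_kg > 0:
            cost_kg = cost / waste_kg
        else:
            procured = list(zip(subset["food_item_id"], subset["served_kg"]))
            cost_kg = category_cost_per_kg(procured, campaign.factors, category)
        per_category[code] = CategoryCost(
            category=category,
            waste_kg=waste_kg,
            cost_per_kg_eur=cost_kg,
            waste_cost_eur=cost,
            servings_count=servings.get(code, 0.0),
        )

    case_cfg = campaign.config.case(case_id)
    case_accounts = [a for a in accounts if a.case_id == case_id]
    days = len({a.date for a in case_accounts})
    meals = case_cfg.meals_served
    if meals is None:
        by_date: dict[str, int] = {}
        for a in case_accounts:
            by_date[a.date] = max(by_date.get(a.date, 0), a.children)
        meals = sum(by_date.values())
    return CostAccount(
        case_id=case_id,
        per_category=per_category,
        days=days,
        meals=meals,
        full_price_eur=case_cfg.full_price_eur,
        procurement_budget_eur=case_cfg.procurement_budget_eur,
    )


def cost_table(accounts: Sequence[CostAccount]) -> pd.DataFrame:
    """Cost table: one row per category plus a total row with derived metrics."""
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
                    "cost_per_kg_eur": cat.cost_per_kg_eur,
                    "waste_cost_eur": cat.waste_cost_eur,
                    "cost_per_serving_eur": cat.cost_per_serving_eur,
                }
            )
        metrics = account.metrics
        rows.append(
            {
                "case_id": account.case_id,
                "category": "total",
                "waste_kg": account.total_waste_kg,
                "cost_per_kg_eur": metrics["cost_per_kg_eur"],
                "waste_cost_eur": account.total_cost_eur,
                "cost_per_serving_eur": metrics["cost_per_meal_eur"],
                "daily_cost_eur": metrics["daily_cost_eur"],
                "share_of_full_price_pct": metrics["share_of_full_price_pct"],
                "share_of_procurement_budget_pct": metrics["share_of_procurement_budget_pct"],
            }
        )
    return pd.DataFrame(rows)
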