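"""Served amounts, waste percentages, waste per child and intake per child.

The atomic unit is a :class:`CategoryDayAccount`: one food category on one
collection day of one case, pooled across the schools of that case (daily
statistics are computed over collection days, which is also the unit the
comparison stage tests on).  Served mass comes from the dish library (average
weighed serving x children), waste mass from the aggregate bin weighings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import Campaign, DishServing, FoodCategory, CATEGORY_CODES
from .errors import DataQualityWarning, UndefinedRatioError, ValidationError

#: Categories excluded from between-case testing (too few serving days).
EXCLUDED_FROM_TESTING: tuple[str, ...] = (FoodCategory.OTHER.value, FoodCategory.DESSERT.value)


def served_mass(dish: DishServing, children: int) -> float:
    """Grams served for one dish: average edible serving times children."""
    if children < 1:
        raise ValidationError("children must be >= 1")
    if dish.avg_serving_g <= 0:
        raise ValidationError(f"dish {dish.dish_id}: non-positive serving mass")
    return dish.avg_serving_g * children


def waste_percentage(waste_g: float, served_g: float) -> float:
    """Waste as a percentage of the served amount."""
    if served_g <= 0:
        raise UndefinedRatioError("waste percentage undefined for zero served mass")
    return 100.0 * waste_g / served_g


def per_child(mass_g: float, children: int) -> float:
    """Mass divided over the children served."""
    if children < 1:
        raise ValidationError("children must be >= 1")
    return mass_g / children


def intake_per_child(avg_serving_g: float, waste_per_child_g: float) -> tuple[float, bool]:
    """Average serving minus waste per child, floored at zero.

    Returns ``(value, flagged)``; ``flagged`` is True when the raw difference
    was negative (aggregate weighing can exceed the nominal serving when
    children take extra food), in which case a :class:`DataQualityWarning`
    is emitted and the value is floored at 0.
    """
    if avg_serving_g < 0 or waste_per_child_g < 0:
        raise ValidationError("masses must be non-negative")
    raw = avg_serving_g - waste_per_child_g
    if raw < 0:
        warnings.warn(
            f"intake per child floored at 0 (serving {avg_serving_g:.1f} g < "
            f"waste {waste_per_child_g:.1f} g)",
            DataQualityWarning,
            stacklevel=2,
        )
        return 0.0, True
    return raw, False


@dataclass(frozen=True)
class CategoryDayAccount:
    """One category on one collection day of one case (schools pooled)."""

    date: str
    case_id: str
    category: FoodCategory
    served_g: float
    waste_g: float
    children: int
    n_dishes: int
    waste_pct: float
    avg_serving_g: float  # children-weighted mean serving across schools/dishes
    waste_per_child_g: float
    intake_per_child_g: float
    flags: tuple[str, ...] = ()


def build_day_accounts(campaign: Campaign) -> list[CategoryDayAccount]:
    """Assemble one account per (date, case, category) from a loaded campaign.

    Served mass is the dish-level sum (several dishes of one category on the
    same day all contribute); waste is observed only at category level, per
    the aggregate selective weighing protocol.  Waste above the served mass
    is flagged, never clipped.
    """
    menus = campaign.menus.copy()
    menus["category"] = [campaign.dishes[d].category.value for d in menus["dish_id"]]
    menus["avg_serving_g"] = [campaign.dishes[d].avg_serving_g for d in menus["dish_id"]]

    children_lookup = {
        (r.date, r.school_id, r.category): r.children_served
        for r in campaign.observations.itertuples(index=False)
    }

    accounts: list[CategoryDayAccount] = []
    grouped = campaign.observations.groupby(["date", "case_id", "category"], sort=True)
    for (date, case_id, category), obs in grouped:
        waste_g = float(obs["waste_mass_g"].sum())
        children = int(obs["children_served"].sum())
        served_g = 0.0
        n_dishes = 0
        for school_id in obs["school_id"]:
            school_children = children_lookup[(date, school_id, category)]
            mask = (
                (menus["date"] == date)
                & (menus["school_id"] == school_id)
                & (menus["category"] == category)
            )
            for serving in menus.loc[mask, "avg_serving_g"]:
                served_g += serving * school_children
                n_dishes += 1

        flags: list[str] = []
        pct = waste_percentage(waste_g, served_g)
        if pct > 100.0:
            flags.append("waste_exceeds_served")
            warnings.warn(
                f"{date} {case_id} {category}: waste {waste_g:.0f} g exceeds "
                f"served {served_g:.0f} g",
                DataQualityWarning,
                stacklevel=2,
            )
        waste_pc = per_child(waste_g, children)
        avg_serving = served_g / children
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DataQualityWarning)
            intake_pc, floored = intake_per_child(avg_serving, waste_pc)
        if floored:
            flags.append("intake_floored")

        accounts.append(
            CategoryDayAccount(
                date=date,
                case_id=case_id,
                category=FoodCategory(category),
                served_g=served_g,
                waste_g=waste_g,
                children=children,
                n_dishes=n_dishes,
                waste_pct=pct,
                avg_serving_g=avg_serving,
                waste_per_child_g=waste_pc,
                intake_per_child_g=intake_pc,
                flags=tuple(flags),
            )
        )
    return accounts


@dataclass(frozen=True)
class CategoryTotals:
    category: FoodCategory
    n_dishes: int
    n_days: int
    served_kg: float
    waste_kg: float
    waste_pct: float  # pooled: total waste / total served
    mean_serving_g: float


@dataclass
class CaseWasteSummary:
    """Per-category and total aggregates plus the per-day series of one case."""

    case_id: str
    n_days: int
    total_children_lunches: int  # sum over days of children served a lunch
    per_category: dict[str, CategoryTotals]
    total_served_kg: float
    total_waste_kg: float
    total_waste_pct: float
    daily: pd.DataFrame  # columns: date, category ('total' row included),
    #                      served_g, waste_g, waste_pct, waste_per_child_g,
    #                      intake_per_child_g, children
    flags: tuple[str, ...] = ()

    def daily_series(self, category: str, column: str) -> np.ndarray:
        """Per-collection-day series for one category (or 'total')."""
        mask = self.daily["category"] == category
        return self.daily.loc[mask].sort_values("date")[column].to_numpy(dtype=float)


def aggregate_case(accounts: Sequence[CategoryDayAccount], case_id: str | None = None) -> CaseWasteSummary:
    """Aggregate day-level accounts of a single case into campaign totals.

    Totals are plain sums over days, schools and dishes; the daily frame keeps
    one row per (collection day, category) plus a per-day 'total' row, which
    is what the descriptive statistics and the between-case tests consume.
    """
    # canonical order makes float sums exactly permutation-invariant
    accounts = sorted(accounts, key=lambda a: (a.date, a.category.value))
    if not accounts:
        raise ValidationError("no accounts to aggregate")
    case_ids = {a.case_id for a in accounts}
    if case_id is None:
        if len(case_ids) > 1:
            raise ValidationError(f"mixed case ids in accounts: {sorted(case_ids)}")
        case_id = accounts[0].case_id
    elif case_ids != {case_id}:
        raise ValidationError(f"accounts for {sorted(case_ids)} do not match case {case_id!r}")

    daily_rows = []
    for a in sorted(accounts, key=lambda a: (a.date, a.category.value)):
        daily_rows.append(
            {
                "date": a.date,
                "category": a.category.value,
                "served_g": a.served_g,
                "waste_g": a.waste_g,
                "children": a.children,
                "waste_pct": a.waste_pct,
                "waste_per_child_g": a.waste_per_child_g,
                "intake_per_child_g": a.intake_per_child_g,
            }
        )

    # per-day totals across categories; children counted once per day as the
    # maximum per-category head count (the same children eat every course)
    by_date: dict[str, list[CategoryDayAccount]] = {}
    for a in accounts:
        by_date.setdefault(a.date, []).append(a)
    for date, day_accounts in sorted(by_date.items()):
        served = sum(a.served_g for a in day_accounts)
        waste = sum(a.waste_g for a in day_accounts)
        children = max(a.children for a in day_accounts)
        daily_rows.append(
            {
                "date": date,
                "category": "total",
                "served_g": served,
                "waste_g": waste,
                "children": children,
                "waste_pct": waste_percentage(waste, served),
                "waste_per_child_g": per_child(waste, children),
                "intake_per_child_g": per_child(served - waste, children)
                if served >= waste
                else 0.0,
            }
        )
    daily = pd.DataFrame(daily_rows)

    per_category: dict[str, CategoryTotals] = {}
    for code in CATEGORY_CODES:
        cat_accounts = [a for a in accounts if a.category.value == code]
        if not cat_accounts:
            continue
        served_g = sum(a.served_g for a in cat_accounts)
        waste_g = sum(a.waste_g for a in cat_accounts)
        children = sum(a.children for a in cat_accounts)
        per_category[code] = CategoryTotals(
            category=FoodCategory(code),
            n_dishes=sum(a.n_dishes for a in cat_accounts),
            n_days=len(cat_accounts),
            served_kg=served_g / 1000.0,
            waste_kg=waste_g / 1000.0,
            waste_pct=waste_percentage(waste_g, served_g),
            mean_serving_g=served_g / children,
        )

    total_served_g = sum(a.served_g for a in accounts)
    total_waste_g = sum(a.waste_g for a in accounts)
    flags = tuple(sorted({f for a in accounts for f in a.flags}))
    total_children = int(
        daily.loc[daily["category"] == "total", "children"].sum()
    )
    return CaseWasteSummary(
        case_id=case_id,
        n_days=len(by_date),
        total_children_lunches=total_children,
        per_category=per_category,
        total_served_kg=total_served_g / 1000.0,
        total_waste_kg=total_waste_g / 1000.0,
        total_waste_pct=waste_percentage(total_waste_g, total_served_g),
        daily=daily,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# aggregate-waste reconstruction shared by the carbon and cost stages
# ---------------------------------------------------------------------------

def decompose_waste_to_items(
    campaign: Campaign, accounts: Sequence[CategoryDayAccount], case_id: str
) -> pd.DataFrame:
    """Allocate each category-day's aggregate waste across recipe items.

    Waste within a category-day is split across food items proportionally to
    the served item mix of that category-day (the same reconstruction the
    nutrition stage uses at profile level).  Returns one row per
    (category, food_item_id) with campaign-total ``served_kg`` and ``waste_kg``.
    """
    rows: dict[tuple[str, str], dict[str, float]] = {}
    children_lookup = {
        (r.date, r.school_id, r.category): r.children_served
        for r in campaign.observations.itertuples(index=False)
    }
    obs = campaign.observations
    menus = campaign.menus
    for account in accounts:
        if account.case_id != case_id:
            continue
        category = account.category.value
        # grams of each item served that day, summed over schools and dishes
        item_served: dict[str, float] = {}
        day_obs = obs[(obs["date"] == account.date) & (obs["case_id"] == case_id)
                      & (obs["category"] == category)]
        for school_id in day_obs["school_id"]:
            children = children_lookup[(account.date, school_id, category)]
            mask = (menus["date"] == account.date) & (menus["school_id"] == school_id)
            for dish_id in menus.loc[mask, "dish_id"]:
                dish = campaign.dishes[dish_id]
                if dish.category.value != category:
                    continue
                for item_id, grams in dish.recipe:
                    item_served[item_id] = item_served.get(item_id, 0.0) + grams * children
        recipe_total = sum(item_served.values())
        if recipe_total <= 0:
            raise ValidationError(
                f"{account.date} {category}: no recipe mass to allocate waste over"
            )
        waste_fraction = account.waste_g / account.served_g
        for item_id, grams in item_served.items():
            key = (category, item_id)
            cell = rows.setdefault(key, {"served_g": 0.0, "waste_g": 0.0})
            # item-level served mass re-scaled so category items sum to the
            # measured served mass (recipe masses fix proportions only)
            scaled = grams / recipe_total * account.served_g
            cell["served_g"] += scaled
            cell["waste_g"] += waste_fraction * scaled

    out = pd.DataFrame(
        [
            {
                "category": category,
                "food_item_id": item_id,
                "served_kg": cell["served_g"] / 1000.0,
                "waste_kg": cell["waste_g"] / 1000.0,
            }
            for (category, item_id), cell in sorted(rows.items())
        ]
    )
    return out


def waste_table(summaries: Sequence[CaseWasteSummary]) -> pd.DataFrame:
    """Per-category counts/masses table (one row per category plus a total row
    per case)."""
    rows = []
    for s in summaries:
        for code in CATEGORY_CODES:
            totals = s.per_category.get(code)
            rows.append(
                {
                    "case_id": s.case_id,
                    "category": code,
                    "n_dishes": 0 if totals is None else totals.n_dishes,
                    "n_days": 0 if totals is None else totals.n_days,
                    "served_kg": 0.0 if totals is None else totals.served_kg,
                    "waste_kg": 0.0 if totals is None else totals.waste_kg,
                    "waste_kg_per_day": 0.0 if totals is None else totals.waste_kg / s.n_days,
                }
            )
        rows.append(
            {
                "case_id": s.case_id,
                "category": "total",
                "n_dishes": sum(t.n_dishes for t in s.per_category.values()),
                "n_days": s.n_days,
                "served_kg": s.total_served_kg,
                "waste_kg": s.total_waste_kg,
                "waste_kg_per_day": s.total_waste_kg / s.n_days,
            }
        )
    return pd.DataFrame(rows)


def waste_percentage_table(summaries: Sequence[CaseWasteSummary]) -> pd.DataFrame:
    """Serving size / waste-% / waste-per-child descriptive table per category."""
    rows = []
    for s in summaries:
        for code in [*CATEGORY_CODES, "total"]:
            mask = s.daily["category"] == code
            if not mask.any():
                continue
            sub = s.daily.loc[mask]
            rows.append(
                {
                    "case_id": s.case_id,
                    "category": code,
                    "n_days": int(mask.sum()),
                    "mean_serving_g": (
                        float(sub["served_g"].sum() / sub["children"].sum())
                    ),
                    "median_waste_pct": float(sub["waste_pct"].median()),
                    "waste_pct_q1": float(sub["waste_pct"].quantile(0.25)),
                    "waste_pct_q3": float(sub["waste_pct"].quantile(0.75)),
                    "median_waste_per_child_g": float(sub["waste_per_child_g"].median()),
                }
            )
    return pd.DataFrame(rows)
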