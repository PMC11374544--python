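"""Energy and nutrient content of served, wasted and consumed meals.

All menu-level profiles are normalised *per child per lunch*.  The nutrient
content of the aggregate waste bin is reconstructed by assuming waste is
compositionally identical to the served mix of its category on that day, so
``wasted = waste_fraction x served`` holds component-wise within a category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import Campaign, CompositionRecord, DishServing
from .errors import DataQualityWarning, IntegrityError, ValidationError
from .nutrients import COMPONENTS, NutrientProfile
from .waste_accounting import CategoryDayAccount


def dish_profile(dish: DishServing, composition: Mapping[str, CompositionRecord]) -> NutrientProfile:
    """Nutrient profile of one serving: sum of (grams/100) x per-100g profiles."""
    total = NutrientProfile.zeros()
    for item_id, grams in dish.recipe:
        record = composition.get(item_id)
        if record is None:
            raise IntegrityError(f"recipe item {item_id!r} has no composition record")
        total = total + record.profile_per_100g * (grams / 100.0)
    return total


def waste_profile(
    category_waste_g: float,
    category_served_g: float,
    served_category_profile: NutrientProfile,
) -> NutrientProfile:
    """Nutrients in the aggregate waste of one category.

    The waste bin is assigned the nutrient density of the served category mix:
    ``(waste_g / served_g) x served-category profile``.
    """
    if category_served_g <= 0:
        if category_waste_g > 0:
            raise ValidationError("nonzero waste with zero served mass")
        return NutrientProfile.zeros()
    return served_category_profile * (category_waste_g / category_served_g)


@dataclass(frozen=True)
class MenuNutrition:
    """Per-child served/wasted/intake profiles for one menu day of one case."""

    date: str
    case_id: str
    served: NutrientProfile
    wasted: NutrientProfile
    intake: NutrientProfile
    loss_pct: dict[str, float]  # NaN where the served component is zero
    flags: tuple[str, ...] = ()


def _served_category_profiles(
    campaign: Campaign, date: str, case_id: str
) -> tuple[dict[str, NutrientProfile], int]:
    """Per-child served profile of each category that day (children-weighted
    across the schools of the case), plus the day's head count."""
    obs = campaign.observations
    day_obs = obs[(obs["date"] == date) & (obs["case_id"] == case_id)]
    if day_obs.empty:
        raise ValidationError(f"no observations for {case_id} on {date}")
    children_by_school_cat = {
        (r.school_id, r.category): r.children_served
        for r in day_obs.itertuples(index=False)
    }
    totals: dict[str, NutrientProfile] = {}
    children_by_cat: dict[str, int] = {}
    for (school_id, category), children in children_by_school_cat.items():
        for dish in campaign.dishes_on(date, school_id):
            if dish.category.value != category:
                continue
            profile = dish_profile(dish, campaign.composition) * children
            totals[category] = totals.get(category, NutrientProfile.zeros()) + profile
    for (school_id, category), children in children_by_school_cat.items():
        children_by_cat[category] = children_by_cat.get(category, 0) + children
    per_child = {
        category: totals[category] * (1.0 / children_by_cat[category])
        for category in totals
    }
    head_count = max(children_by_school_cat.values())
    return per_child, head_count


def menu_nutrition(
    campaign: Campaign,
    accounts: Sequence[CategoryDayAccount],
    date: str,
    case_id: str,
) -> MenuNutrition:
    """Served, wasted and actual-intake profiles per child for one menu day.

    ``served`` sums the per-child category profiles; ``wasted`` scales each by
    its category waste fraction; ``intake = served - wasted`` floored at zero
    (flooring is flagged, and only occurs when waste exceeded the served mass).
    """
    category_profiles, _ = _served_category_profiles(campaign, date, case_id)
    day_accounts = {
        a.category.value: a for a in accounts if a.date == date and a.case_id == case_id
    }
    if set(day_accounts) != set(category_profiles):
        raise ValidationError(
            f"{date} {case_id}: accounts cover {sorted(day_accounts)} but menu has "
            f"{sorted(category_profiles)}"
        )
    served = NutrientProfile.zeros()
    wasted = NutrientProfile.zeros()
    flags: list[str] = []
    for category, profile in category_profiles.items():
        account = day_accounts[category]
        served = served + profile
        wasted = wasted + waste_profile(account.waste_g, account.served_g, profile)
        flags.extend(account.flags)
    raw_intake = served.diff(wasted)
    if np.any(raw_intake < -1e-9):
        flags.append("intake_floored")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DataQualityWarning)
        intake = served - wasted
    loss = {}
    for name in COMPONENTS:
        s = served[name]
        loss[name] = 100.0 * wasted[name] / s if s > 0 else float("nan")
    return MenuNutrition(
        date=date,
        case_id=case_id,
        served=served,
        wasted=wasted,
        intake=intake,
        loss_pct=loss,
        flags=tuple(sorted(set(flags))),
    )


def case_nutrition(
    campaign: Campaign, accounts: Sequence[CategoryDayAccount], case_id: str
) -> list[MenuNutrition]:
    """One :class:`MenuNutrition` per collection day of the case."""
    return [
        menu_nutrition(campaign, accounts, date, case_id)
        for date in campaign.dates(case_id)
    ]


def nutrition_table(menus: Sequence[MenuNutrition]) -> pd.DataFrame:
    """Served/waste/intake descriptives per component over the menu days.

    Both mean +/- SD and median (Q1, Q3) are emitted; which one a report
    should quote depends on the normality verdict of the comparison stage.
    """
    rows = []
    if not menus:
        return pd.DataFrame(
            columns=["case_id", "component", "basis", "mean", "sd", "median", "q1", "q3"]
        )
    case_id = menus[0].case_id
    for basis in ("served", "wasted", "intake"):
        for name in COMPONENTS:
            series = np.array([getattr(m, basis)[name] for m in menus])
            rows.append(
                {
                    "case_id": case_id,
                    "component": name,
                    "basis": basis,
                    "mean": float(series.mean()),
                    "sd": float(series.std(ddof=1)) if len(series) > 1 else 0.0,
                    "median": float(np.median(series)),
                    "q1": float(np.percentile(series, 25)),
                    "q3": float(np.percentile(series, 75)),
                }
            )
    return pd.DataFrame(rows)


def loss_table(menus: Sequence[MenuNutrition]) -> pd.DataFrame:
    """Percentage losses per component (energy/macros and micros alike)."""
    rows = []
    if not menus:
        return pd.DataFrame(columns=["case_id", "component", "mean", "sd", "median", "q1", "q3"])
    case_id = menus[0].case_id
    for name in COMPONENTS:
        series = np.array([m.loss_pct[name] for m in menus], dtype=float)
        series = series[~np.isnan(series)]
        if series.size == 0:
            continue
        rows.append(
            {
                "case_id": case_id,
                "component": name,
                "mean": float(series.mean()),
                "sd": float(series.std(ddof=1)) if series.size > 1 else 0.0,
                "median": float(np.median(series)),
                "q1": float(np.percentile(series, 25)),
                "q3": float(np.percentile(series, 75)),
            }
        )
    return pd.DataFrame(rows)
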