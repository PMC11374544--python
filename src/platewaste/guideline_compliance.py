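"""Menu-by-menu evaluation against school-lunch guideline bounds.

Bounds are closed intervals: a value exactly equal to a bound is compliant.
Quantities are either profile components or derived energy shares
(protein/fat/carbohydrate as percent of energy, Atwater 4/9/4).
Verdicts are per menu-day; shares are the percentage of menu-days whose value
lies within the bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .data_io import GuidelineBound, GuidelineBounds, DERIVED_QUANTITIES
from .errors import UndefinedRatioError, ValidationError
from .nutrients import COMPONENTS, NutrientProfile
from .nutrition_profiling import MenuNutrition

BASES = ("as_served", "as_consumed")

_ATWATER_KCAL_PER_G = {"protein_energy_pct": ("protein_g", 4.0),
                       "fat_energy_pct": ("fat_g", 9.0),
                       "carbohydrate_energy_pct": ("carbohydrate_g", 4.0)}


def evaluate_quantity(profile: NutrientProfile, quantity: str) -> float:
    """Value of a guideline quantity on a profile (component or energy share)."""
    if quantity in COMPONENTS:
        return profile[quantity]
    if quantity in DERIVED_QUANTITIES:
        component, kcal_per_g = _ATWATER_KCAL_PER_G[quantity]
        energy = profile["energy_kcal"]
        if energy <= 0:
            raise UndefinedRatioError(f"{quantity}: menu has zero energy")
        return 100.0 * profile[component] * kcal_per_g / energy
    raise ValidationError(f"unknown guideline quantity {quantity!r}")


def classify(value: float, bound: GuidelineBound) -> str:
    """'below' / 'within' / 'above' for a closed-interval bound."""
    if bound.lower is not None and value < bound.lower:
        return "below"
    if bound.upper is not None and value > bound.upper:
        return "above"
    return "within"


@dataclass(frozen=True)
class ComplianceResult:
    """Verdicts of one menu day on one basis."""

    date: str
    case_id: str
    basis: str  # as_served | as_consumed
    verdicts: dict[str, str]  # quantity -> below|within|above|no_bound
    values: dict[str, float]


def check_menu(menu: MenuNutrition, bounds: GuidelineBounds, basis: str) -> ComplianceResult:
    """Evaluate one menu day against every bound applicable on *basis*."""
    if basis not in BASES:
        raise ValidationError(f"basis must be one of {BASES}, got {basis!r}")
    profile = menu.served if basis == "as_served" else menu.intake
    verdicts: dict[str, str] = {}
    values: dict[str, float] = {}
    for quantity in (*COMPONENTS, *DERIVED_QUANTITIES):
        bound = bounds.get(quantity)
        if bound is None or (bound.basis != "both" and bound.basis != basis):
            verdicts[quantity] = "no_bound"
            continue
        value = evaluate_quantity(profile, quantity)
        values[quantity] = value
        verdicts[quantity] = classify(value, bound)
    return ComplianceResult(
        date=menu.date, case_id=menu.case_id, basis=basis, verdicts=verdicts, values=values
    )


def compliance_share(results: Sequence[ComplianceResult], quantity: str) -> Optional[float]:
    """Percent of menus whose *quantity* verdict is 'within'.

    Returns None when no menu had a bound for the quantity.
    """
    if not results:
        raise ValidationError("no compliance results")
    bounded = [r for r in results if r.verdicts.get(quantity, "no_bound") != "no_bound"]
    if not bounded:
        return None
    within = sum(1 for r in bounded if r.verdicts[quantity] == "within")
    return 100.0 * within / len(bounded)


def compliance_table(results: Sequence[ComplianceResult]) -> pd.DataFrame:
    """Share-of-menus-compliant table, one row per (case, basis, quantity)."""
    rows = []
    keys = sorted({(r.case_id, r.basis) for r in results})
    for case_id, basis in keys:
        subset = [r for r in results if r.case_id == case_id and r.basis == basis]
        for quantity in (*COMPONENTS, *DERIVED_QUANTITIES):
            share = compliance_share(subset, quantity)
            if share is None:
                continue
            n_below = sum(1 for r in subset if r.verdicts[quantity] == "below")
            n_above = sum(1 for r in subset if r.verdicts[quantity] == "above")
            rows.append(
                {
                    "case_id": case_id,
                    "basis": basis,
                    "quantity": quantity,
                    "n_menus": len(subset),
                    "share_within_pct": share,
                    "n_below": n_below,
                    "n_above": n_above,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["case_id", "basis", "quantity", "n_menus", "share_within_pct",
                 "n_below", "n_above"],
    )
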