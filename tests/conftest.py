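from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from platewaste.data_io import (
    Campaign,
    CampaignConfig,
    CaseConfig,
    DishServing,
    FactorRow,
    FactorTable,
    FoodCategory,
    GuidelineBound,
    GuidelineBounds,
    validate_campaign,
)
from platewaste.synthetic_data import (
    default_composition,
    generate_campaign,
    paperlike_preset,
)


def make_tiny_campaign(
    waste_starchy_g: float = 550.0,
    waste_fruit_g: float = 500.0,
    children: int = 20,
) -> Campaign:
    """One day, one school, two categories; every number hand-checkable.

    starchy: avg serving 110 g (measurements 100/110/120), 20 children
             -> 2200 g served; fruit: 100 g -> 2000 g served.
    """
    dishes = {
        "A_pasta": DishServing(
            dish_id="A_pasta",
            name="pasta",
            category=FoodCategory.STARCHY,
            serving_measurements_g=(100.0, 110.0, 120.0),
            avg_serving_g=110.0,
            recipe=(("pasta", 90.0), ("tomato_sauce", 30.0)),
        ),
        "A_fruit": DishServing(
            dish_id="A_fruit",
            name="apple",
            category=FoodCategory.FRUIT,
            serving_measurements_g=(100.0, 100.0, 100.0),
            avg_serving_g=100.0,
            recipe=(("apple", 100.0),),
        ),
    }
    composition = {
        k: v for k, v in default_composition().items()
        if k in ("pasta", "tomato_sauce", "apple")
    }
    factors = FactorTable(
        {
            "pasta": FactorRow(production_ef=1.5, transport_ef=0.003, price=1.6),
            "tomato_sauce": FactorRow(production_ef=0.8, transport_ef=0.003, price=1.8),
            "apple": FactorRow(production_ef=0.4, transport_ef=0.003, price=1.8),
        },
        {"composting": 0.05},
    )
    guidelines = GuidelineBounds(
        [GuidelineBound("energy_kcal", 100.0, 400.0, "kcal", "both")]
    )
    config = CampaignConfig(
        cases=(
            CaseConfig(
                case_id="A",
                transport_distance_km=10.0,
                full_price_eur=5.0,
                procurement_budget_eur=1000.0,
            ),
        ),
        disposal_method="composting",
    )
    observations = pd.DataFrame(
        [
            {
                "date": "2023-01-09", "school_id": "s1", "case_id": "A",
                "category": "starchy", "waste_mass_g": waste_starchy_g,
                "children_served": children, "season": "winter",
            },
            {
                "date": "2023-01-09", "school_id": "s1", "case_id": "A",
                "category": "fruit", "waste_mass_g": waste_fruit_g,
                "children_served": children, "season": "winter",
            },
        ]
    )
    menus = pd.DataFrame(
        [
            {"date": "2023-01-09", "school_id": "s1", "dish_id": "A_pasta"},
            {"date": "2023-01-09", "school_id": "s1", "dish_id": "A_fruit"},
        ]
    )
    campaign = Campaign(
        observations=observations,
        menus=menus,
        dishes=dishes,
        composition=composition,
        factors=factors,
        guidelines=guidelines,
        config=config,
    )
    validate_campaign(campaign)
    return campaign


@pytest.fixture
def tiny_campaign() -> Campaign:
    return make_tiny_campaign()


@pytest.fixture(scope="session")
def preset_campaign():
    """One deterministic paper-scale campaign shared across the session."""
    campaign, truth = generate_campaign(paperlike_preset(seed=7))
    return campaign, truth


@pytest.fixture(scope="session")
def preset_accounts(preset_campaign):
    from platewaste.waste_accounting import build_day_accounts

    campaign, _ = preset_campaign
    return build_day_accounts(campaign)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230109)
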