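"""Randomized miniature campaign specs shared by property and acceptance tests."""

from __future__ import annotations

import numpy as np

from platewaste.data_io import CATEGORY_CODES
from platewaste.synthetic_data import CampaignSpec, CaseSpec, CategoryParams


def random_mini_spec(rng: np.random.Generator) -> CampaignSpec:
    """A small single-case spec with random fractions, servings and schedule."""
    params = {}
    concentration = float(rng.uniform(2.0, 50.0))
    for code in CATEGORY_CODES:
        mean = float(rng.uniform(30.0, 150.0))
        params[code] = CategoryParams(
            mean_waste_fraction=float(rng.uniform(0.05, 0.9)),
            concentration=concentration,
            serving_mean_g=mean,
            serving_sd_g=mean * float(rng.uniform(0.0, 0.1)),
        )
    case = CaseSpec(
        case_id="MINI",
        n_days=int(rng.integers(2, 5)),
        n_schools=int(rng.integers(1, 3)),
        children_range=(20, 60),
        category_params=params,
        other_prob=float(rng.uniform(0.0, 0.4)),
        dessert_prob=float(rng.uniform(0.0, 0.4)),
        transport_distance_km=float(rng.uniform(0.0, 30.0)),
        full_price_eur=5.0,
        procurement_budget_eur=2000.0,
    )
    return CampaignSpec(seed=int(rng.integers(2**31)), cases=(case,))
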