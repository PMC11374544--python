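from fractions import Fraction

import numpy as np
import pytest

from platewaste.data_io import DishServing, FoodCategory
from platewaste.errors import DataQualityWarning, UndefinedRatioError, ValidationError
from platewaste.synthetic_data import generate_campaign
from platewaste.waste_accounting import (
    aggregate_case,
    build_day_accounts,
    decompose_waste_to_items,
    intake_per_child,
    per_child,
    served_mass,
    waste_percentage,
    waste_table,
)

from conftest import make_tiny_campaign
from helpers_synth import random_mini_spec


def _dish(avg=120.0, measurements=(120.0, 120.0, 120.0)):
    return DishServing("d", "d", FoodCategory.STARCHY, measurements, avg,
                       (("pasta", 100.0),))


class TestServedMass:
    def test_direct_product(self):
        assert served_mass(_dish(avg=120.0), 100) == 12_000.0

    def test_mean_then_product(self):
        dish = _dish(avg=110.0, measurements=(100.0, 110.0, 120.0))
        assert served_mass(dish, 10) == pytest.approx(1_100.0)

    def test_single_child_identity(self):
        assert served_mass(_dish(avg=120.0), 1) == 120.0

    def test_zero_children_rejected(self):
        with pytest.raises(ValidationError):
            served_mass(_dish(), 0)


class TestWastePercentage:
    @pytest.mark.parametrize(
        "waste,served,expected",
        [(0.0, 5000.0, 0.0), (5000.0, 5000.0, 100.0), (1250.0, 5000.0, 25.0)],
    )
    def test_examples(self, waste, served, expected):
        assert waste_percentage(waste, served) == expected

    def test_zero_served_rejected(self):
        with pytest.raises(UndefinedRatioError):
            waste_percentage(1.0, 0.0)


class TestPerChild:
    def test_examples(self):
        assert per_child(500.0, 5) == 100.0
        assert per_child(0.0, 17) == 0.0

    def test_matches_exact_fraction_oracle(self, rng):
        for _ in range(200):
            waste = int(rng.integers(0, 10_000))
            children = int(rng.integers(1, 400))
            assert per_child(float(waste), children) == pytest.approx(
                float(Fraction(waste, children)), rel=1e-12
            )


class TestIntakePerChild:
    def test_plain(self):
        assert intake_per_child(150.0, 50.0) == (100.0, False)

    def test_full_rejection(self):
        assert intake_per_child(150.0, 150.0) == (0.0, False)

    def test_floored_with_flag(self):
        with pytest.warns(DataQualityWarning):
            value, flagged = intake_per_child(150.0, 160.0)
        assert value == 0.0 and flagged


class TestBuildDayAccounts:
    def test_tiny_campaign_numbers(self, tiny_campaign):
        accounts = build_day_accounts(tiny_campaign)
        by_cat = {a.category.value: a for a in accounts}
        starchy = by_cat["starchy"]
        assert starchy.served_g == 110.0 * 20
        assert starchy.waste_pct == pytest.approx(25.0)
        assert starchy.waste_per_child_g == pytest.approx(27.5)
        assert starchy.intake_per_child_g == pytest.approx(110.0 - 27.5)
        assert starchy.flags == ()

    def test_waste_exceeding_served_flagged_not_clipped(self):
        campaign = make_tiny_campaign(waste_starchy_g=3000.0)  # served 2200 g
        with pytest.warns(DataQualityWarning):
            accounts = build_day_accounts(campaign)
        starchy = next(a for a in accounts if a.category.value == "starchy")
        assert starchy.waste_pct > 100.0
        assert "waste_exceeds_served" in starchy.flags
        assert "intake_floored" in starchy.flags
        assert starchy.intake_per_child_g == 0.0

    def test_mass_conservation_per_cell(self, preset_accounts):
        for a in preset_accounts:
            if "intake_floored" in a.flags:
                continue
            assert a.served_g == pytest.approx(
                a.waste_g + a.children * a.intake_per_child_g, rel=1e-9
            )


class TestAggregateCase:
    def test_single_day_identity(self, tiny_campaign):
        accounts = build_day_accounts(tiny_campaign)
        summary = aggregate_case(accounts)
        assert summary.n_days == 1
        assert summary.total_served_kg == pytest.approx((2200.0 + 2000.0) / 1000)
        assert summary.total_waste_kg == pytest.approx((550.0 + 500.0) / 1000)
        assert summary.total_waste_pct == pytest.approx(100 * 1050 / 4200)

    def test_mixed_case_ids_rejected(self, tiny_campaign):
        accounts = build_day_accounts(tiny_campaign)
        with pytest.raises(ValidationError):
            aggregate_case(accounts, case_id="B")

    def test_totals_match_brute_force_sum(self, preset_campaign, preset_accounts):
        campaign, _ = preset_campaign
        summary = aggregate_case(
            [a for a in preset_accounts if a.case_id == "LOC-ORG"], "LOC-ORG"
        )
        obs = campaign.observations
        raw = obs[obs["case_id"] == "LOC-ORG"]["waste_mass_g"].sum()
        assert summary.total_waste_kg == pytest.approx(raw / 1000.0, rel=1e-12)
        assert summary.n_days == 20

    def test_order_invariance(self, preset_accounts, rng):
        accounts = [a for a in preset_accounts if a.case_id == "ORG"]
        shuffled = list(accounts)
        rng.shuffle(shuffled)
        a = aggregate_case(accounts, "ORG")
        b = aggregate_case(shuffled, "ORG")
        assert a.total_served_kg == b.total_served_kg
        assert a.total_waste_kg == b.total_waste_kg
        assert a.daily.sort_values(["date", "category"]).reset_index(drop=True).equals(
            b.daily.sort_values(["date", "category"]).reset_index(drop=True)
        )

    def test_scaling_masses_by_k(self):
        base = make_tiny_campaign(waste_starchy_g=550.0, waste_fruit_g=500.0)
        scaled_obs = base.observations.copy()
        scaled_obs["waste_mass_g"] *= 3.0
        scaled = make_tiny_campaign(waste_starchy_g=1650.0, waste_fruit_g=1500.0)
        s_base = aggregate_case(build_day_accounts(base))
        s_scaled = aggregate_case(build_day_accounts(scaled))
        assert s_scaled.total_waste_kg == pytest.approx(3 * s_base.total_waste_kg)
        # waste % scales with waste only; scaling *all* masses leaves it fixed
        assert s_base.total_waste_pct == pytest.approx(100 * 1050 / 4200)


class TestDecomposition:
    def test_item_masses_sum_to_category_masses(self, preset_campaign, preset_accounts):
        campaign, _ = preset_campaign
        accounts = [a for a in preset_accounts if a.case_id == "ORG"]
        allocation = decompose_waste_to_items(campaign, preset_accounts, "ORG")
        summary = aggregate_case(accounts, "ORG")
        for code, totals in summary.per_category.items():
            subset = allocation[allocation["category"] == code]
            assert subset["waste_kg"].sum() == pytest.approx(totals.waste_kg, rel=1e-9)
            assert subset["served_kg"].sum() == pytest.approx(totals.served_kg, rel=1e-9)


def test_waste_table_has_seven_categories_plus_total(preset_accounts):
    summary = aggregate_case(
        [a for a in preset_accounts if a.case_id == "LOC-ORG"], "LOC-ORG"
    )
    table = waste_table([summary])
    assert len(table) == 8
    assert table["category"].tolist()[-1] == "total"
    cats = table[table["category"] != "total"]
    assert table.loc[table["category"] == "total", "waste_kg"].iloc[0] == pytest.approx(
        cats["waste_kg"].sum()
    )
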