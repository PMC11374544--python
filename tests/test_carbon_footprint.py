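import numpy as np
import pytest

from platewaste.carbon_footprint import (
    case_emissions,
    emissions_table,
    per_serving_factor,
    production_emissions,
    transport_and_disposal_emissions,
    waste_share_of_supply,
)
from platewaste.data_io import FactorRow, FactorTable, FoodCategory
from platewaste.errors import ConfigurationError, IntegrityError, UndefinedRatioError
from platewaste.synthetic_data import generate_campaign, paperlike_preset
from platewaste.waste_accounting import build_day_accounts


@pytest.fixture
def simple_factors():
    return FactorTable(
        {
            "beef": FactorRow(production_ef=3.54, transport_ef=0.002),
            "protein": FactorRow(production_ef=2.0, transport_ef=0.002),
        },
        {"composting": 0.05},
    )


class TestProductionEmissions:
    def test_zero_waste(self, simple_factors):
        assert production_emissions({}, simple_factors, FoodCategory.PROTEIN) == 0.0

    def test_single_item_product(self, simple_factors):
        # 10 kg at the printed protein-dish factor of 3.54 kg CO2e/kg
        out = production_emissions({"beef": 10.0}, simple_factors, FoodCategory.PROTEIN)
        assert out == pytest.approx(35.4)

    def test_mixed_items_match_brute_force(self, simple_factors, rng):
        masses = {"beef": float(rng.uniform(0, 50)), "lentil": float(rng.uniform(0, 50))}
        out = production_emissions(masses, simple_factors, FoodCategory.PROTEIN)
        brute = masses["beef"] * 3.54 + masses["lentil"] * 2.0  # item EF, else category
        assert out == pytest.approx(brute, rel=1e-12)

    def test_missing_factor_names_scope(self):
        factors = FactorTable({}, {"composting": 0.05})
        with pytest.raises(IntegrityError, match="beef"):
            production_emissions({"beef": 1.0}, factors, FoodCategory.PROTEIN)


class TestTransportAndDisposal:
    def test_zero_distance(self, simple_factors):
        transport, disposal = transport_and_disposal_emissions(
            {"beef": 10.0}, simple_factors, FoodCategory.PROTEIN, 0.0, "composting"
        )
        assert transport == 0.0
        assert disposal == pytest.approx(0.5)

    def test_linearity_in_mass(self, simple_factors):
        t1, d1 = transport_and_disposal_emissions(
            {"beef": 5.0}, simple_factors, FoodCategory.PROTEIN, 12.0, "composting"
        )
        t2, d2 = transport_and_disposal_emissions(
            {"beef": 10.0}, simple_factors, FoodCategory.PROTEIN, 12.0, "composting"
        )
        assert t2 == pytest.approx(2 * t1)
        assert d2 == pytest.approx(2 * d1)

    def test_unknown_disposal_method(self, simple_factors):
        with pytest.raises(ConfigurationError, match="pyrolysis"):
            transport_and_disposal_emissions(
                {"beef": 1.0}, simple_factors, FoodCategory.PROTEIN, 1.0, "pyrolysis"
            )


class TestPerServingFactor:
    def test_zero_total(self):
        assert per_serving_factor(0.0, 100) == 0.0

    def test_starchy_bread_mean_convention(self):
        # starchy + bread serving counts (4000, 3514) -> divisor is their mean
        divisor = (4000 + 3514) / 2
        assert divisor == 3757
        assert per_serving_factor(375.7, divisor) == pytest.approx(0.1)

    def test_division_oracle(self, rng):
        for _ in range(100):
            total = float(rng.uniform(0, 500))
            servings = int(rng.integers(1, 5000))
            assert per_serving_factor(total, servings) == total / servings

    def test_zero_servings(self):
        with pytest.raises(UndefinedRatioError):
            per_serving_factor(1.0, 0)


class TestWasteShareOfSupply:
    def test_full_share(self):
        assert waste_share_of_supply(10.0, 10.0) == 100.0

    def test_printed_supply_totals(self):
        # back-derived from the printed 19 % of 3991 and 28 % of 2790 kg CO2e
        assert waste_share_of_supply(758.29, 3991.0) == pytest.approx(19.0, abs=0.01)
        assert waste_share_of_supply(781.2, 2790.0) == pytest.approx(28.0, abs=0.01)

    def test_zero_denominator(self):
        with pytest.raises(UndefinedRatioError):
            waste_share_of_supply(1.0, 0.0)


class TestCaseEmissions:
    def test_additivity(self, preset_campaign, preset_accounts):
        campaign, _ = preset_campaign
        account = case_emissions(campaign, preset_accounts, "ORG")
        total = sum(c.total_kgco2e for c in account.per_category.values())
        assert account.total_kgco2e == pytest.approx(total, rel=1e-12)
        for cat in account.per_category.values():
            assert cat.total_kgco2e == pytest.approx(
                cat.production_kgco2e + cat.transport_kgco2e + cat.disposal_kgco2e
            )

    def test_linearity_under_mass_scaling(self, preset_campaign, preset_accounts):
        """Scaling all waste masses by k scales emissions by k, avg EF fixed."""
        campaign, _ = preset_campaign
        base = case_emissions(campaign, preset_accounts, "LOC-ORG")
        scaled_campaign = generate_campaign(paperlike_preset(seed=7))[0]
        scaled_campaign.observations = scaled_campaign.observations.copy()
        scaled_campaign.observations["waste_mass_g"] *= 0.5
        scaled_accounts = build_day_accounts(scaled_campaign)
        scaled = case_emissions(scaled_campaign, scaled_accounts, "LOC-ORG")
        assert scaled.total_kgco2e == pytest.approx(0.5 * base.total_kgco2e, rel=1e-9)
        for code, cat in base.per_category.items():
            assert scaled.per_category[code].ef_per_kg_waste == pytest.approx(
                cat.ef_per_kg_waste, rel=1e-9
            )

    def test_category_ef_ordering(self, preset_campaign, preset_accounts):
        """Protein dishes carry the highest per-kg EF; fruit/veg the lowest."""
        campaign, _ = preset_campaign
        for case_id in ("LOC-ORG", "ORG"):
            account = case_emissions(campaign, preset_accounts, case_id)
            efs = {c: v.ef_per_kg_waste for c, v in account.per_category.items()}
            assert efs["protein"] == max(efs.values())
            assert min(efs, key=efs.get) in ("fruit", "vegetable")

    def test_component_shares_are_small(self, preset_campaign, preset_accounts):
        """Transport and disposal are minor components, as in the study design."""
        campaign, _ = preset_campaign
        for case_id in ("LOC-ORG", "ORG"):
            account = case_emissions(campaign, preset_accounts, case_id)
            assert 0.01 <= account.transport_kgco2e / account.total_kgco2e <= 0.10
            assert 0.01 <= account.disposal_kgco2e / account.total_kgco2e <= 0.10

    def test_production_share_below_all_components_share(
        self, preset_campaign, preset_accounts
    ):
        campaign, _ = preset_campaign
        account = case_emissions(campaign, preset_accounts, "ORG")
        assert (
            account.waste_share_of_supply_pct < account.waste_share_all_components_pct
        )
        assert account.per_meal_production_kgco2e < account.per_meal_total_kgco2e


def test_emissions_table_total_rows(preset_campaign, preset_accounts):
    campaign, _ = preset_campaign
    accounts = [case_emissions(campaign, preset_accounts, c) for c in ("LOC-ORG", "ORG")]
    table = emissions_table(accounts)
    for case_id in ("LOC-ORG", "ORG"):
        sub = table[table["case_id"] == case_id]
        total_row = sub[sub["category"] == "total"].iloc[0]
        cats = sub[sub["category"] != "total"]
        assert total_row["total_kgco2e"] == pytest.approx(cats["total_kgco2e"].sum())
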