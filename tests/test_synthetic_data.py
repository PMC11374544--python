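import dataclasses
import json
import math

import numpy as np
import pytest

from platewaste.errors import ValidationError
from platewaste.pipeline import compute_results
from platewaste.synthetic_data import (
    CampaignSpec,
    CaseSpec,
    CategoryParams,
    generate_campaign,
    paperlike_preset,
    validate_spec,
    write_generated,
)
from platewaste.waste_accounting import aggregate_case, build_day_accounts

from helpers_synth import random_mini_spec


def _uniform_case(fraction: float, concentration: float = math.inf) -> CaseSpec:
    params = {
        code: CategoryParams(fraction, concentration, 100.0, 0.0)
        for code in ("starchy", "bread", "protein", "vegetable", "fruit",
                     "dessert", "other")
    }
    return CaseSpec(
        case_id="U", n_days=4, n_schools=2, children_range=(30, 50),
        category_params=params, other_prob=0.2, dessert_prob=0.2,
        full_price_eur=5.0, procurement_budget_eur=1000.0,
    )


class TestSpecValidation:
    def test_fraction_out_of_range(self):
        case = dataclasses.replace(
            _uniform_case(0.5),
            category_params={
                **_uniform_case(0.5).category_params,
                "fruit": CategoryParams(1.2, 10.0, 100.0, 5.0),
            },
        )
        with pytest.raises(ValidationError, match="fraction"):
            validate_spec(CampaignSpec(seed=0, cases=(case,)))

    def test_serving_sd_too_large(self):
        case = dataclasses.replace(
            _uniform_case(0.5),
            category_params={
                **_uniform_case(0.5).category_params,
                "bread": CategoryParams(0.2, 10.0, 100.0, 50.0),
            },
        )
        with pytest.raises(ValidationError, match="SD"):
            validate_spec(CampaignSpec(seed=0, cases=(case,)))

    def test_missing_category(self):
        params = _uniform_case(0.5).category_params.copy()
        del params["dessert"]
        case = dataclasses.replace(_uniform_case(0.5), category_params=params)
        with pytest.raises(ValidationError, match="dessert"):
            validate_spec(CampaignSpec(seed=0, cases=(case,)))


class TestGenerateCampaign:
    def test_zero_fraction_spec_zero_everywhere(self):
        spec = CampaignSpec(seed=5, cases=(_uniform_case(0.0),))
        campaign, truth = generate_campaign(spec)
        assert (campaign.observations["waste_mass_g"] == 0.0).all()
        results = compute_results(campaign)
        case = results["summary"]["cases"]["U"]
        assert case["total_waste_kg"] == 0.0
        assert case["waste_total_kgco2e"] == 0.0
        assert case["waste_cost_eur"] == 0.0

    def test_degenerate_half_fraction(self):
        """concentration = inf plants every daily waste at exactly half the serving."""
        spec = CampaignSpec(seed=6, cases=(_uniform_case(0.5),))
        campaign, truth = generate_campaign(spec)
        accounts = build_day_accounts(campaign)
        for a in accounts:
            assert a.waste_pct == pytest.approx(50.0, rel=1e-12)

    def test_ground_truth_exact_on_degenerate_spec(self):
        spec = CampaignSpec(seed=8, cases=(_uniform_case(0.37),))
        campaign, truth = generate_campaign(spec)
        results = compute_results(campaign)
        case = results["summary"]["cases"]["U"]
        expected = truth["cases"]["U"]
        assert case["total_waste_kg"] == pytest.approx(
            expected["expected_total_waste_kg"], rel=1e-9
        )
        assert case["total_waste_pct"] == pytest.approx(
            expected["expected_total_waste_pct"], rel=1e-9
        )
        assert case["waste_cost_eur"] == pytest.approx(
            expected["expected_waste_cost_eur"], rel=1e-9
        )
        assert case["waste_production_kgco2e"] == pytest.approx(
            expected["expected_waste_production_kgco2e"], rel=1e-9
        )

    def test_determinism_in_memory(self):
        spec = paperlike_preset(seed=33)
        a, truth_a = generate_campaign(spec)
        b, truth_b = generate_campaign(spec)
        assert a.equals(b)
        assert truth_a == truth_b

    def test_determinism_on_disk(self, tmp_path):
        spec = paperlike_preset(seed=34)
        for sub in ("x", "y"):
            campaign, truth = generate_campaign(spec)
            write_generated(campaign, truth, tmp_path / sub)
        for name in sorted(p.name for p in (tmp_path / "x").iterdir()):
            assert (tmp_path / "x" / name).read_bytes() == (
                tmp_path / "y" / name
            ).read_bytes(), name

    def test_seeds_differ(self):
        a, _ = generate_campaign(paperlike_preset(seed=1))
        b, _ = generate_campaign(paperlike_preset(seed=2))
        assert not a.equals(b)


class TestPaperlikePreset:
    def test_scale_matches_study_design(self):
        spec = paperlike_preset()
        assert [case.n_days for case in spec.cases] == [20, 19]
        assert all(case.n_schools == 2 for case in spec.cases)
        fruit_b = spec.cases[1].category_params["fruit"].mean_waste_fraction
        veg_b = spec.cases[1].category_params["vegetable"].mean_waste_fraction
        assert fruit_b > 0.5 and veg_b > 0.5

    def test_planted_case_difference_detected(self, preset_campaign, preset_accounts):
        from platewaste.comparative_stats import compare_cases

        campaign, _ = preset_campaign
        s_a = aggregate_case(
            [a for a in preset_accounts if a.case_id == "LOC-ORG"], "LOC-ORG"
        )
        s_b = aggregate_case([a for a in preset_accounts if a.case_id == "ORG"], "ORG")
        assert s_b.total_waste_pct > s_a.total_waste_pct
        result = compare_cases(
            s_a.daily_series("total", "waste_pct"),
            s_b.daily_series("total", "waste_pct"),
            "total:waste_pct",
        )
        assert result.p_value < 0.05

    def test_expected_totals_near_paper_scale(self, preset_campaign):
        _, truth = preset_campaign
        assert truth["cases"]["LOC-ORG"]["expected_total_waste_pct"] == pytest.approx(
            24.0, abs=2.0
        )
        assert truth["cases"]["ORG"]["expected_total_waste_pct"] == pytest.approx(
            42.0, abs=2.0
        )


def test_parameter_recovery_long_run():
    """Pooled per-category waste fractions converge to the planted means.

    The pooled estimator is a served-mass-weighted mean of the per-cell Beta
    draws, so its Monte-Carlo SE is sd(Beta) * sqrt(sum w^2) / sum w.
    """
    spec = paperlike_preset(seed=4, n_days=(200, 200))
    campaign, truth = generate_campaign(spec)
    accounts = build_day_accounts(campaign)
    obs = campaign.observations
    for case in spec.cases:
        summary = aggregate_case(
            [a for a in accounts if a.case_id == case.case_id], case.case_id
        )
        sub = obs[obs["case_id"] == case.case_id]
        for code, totals in summary.per_category.items():
            planted = case.category_params[code].mean_waste_fraction
            conc = case.category_params[code].concentration
            weights = sub.loc[sub["category"] == code, "children_served"].to_numpy(
                dtype=float
            )
            sd_beta = math.sqrt(planted * (1 - planted) / (conc + 1))
            se = sd_beta * math.sqrt((weights**2).sum()) / weights.sum()
            estimate = totals.waste_kg / totals.served_kg
            assert abs(estimate - planted) < 2 * se, (case.case_id, code)


def test_random_mini_specs_generate_and_validate(rng):
    for _ in range(10):
        campaign, truth = generate_campaign(random_mini_spec(rng))
        assert len(campaign.observations) > 0
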