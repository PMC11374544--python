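"""End-to-end orchestration: load -> account -> profile -> check -> report.

Stages communicate only via files, so any stage can be re-run standalone on
user-supplied data; :func:`run_pipeline` chains them and records a manifest
(input digests, per-stage timings, output digests) for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .data_io import Campaign, CATEGORY_CODES, load_campaign, write_report_tables
from .nutrients import COMPONENTS
from .waste_accounting import (
    CategoryDayAccount,
    aggregate_case,
    build_day_accounts,
    waste_table,
    waste_percentage_table,
    EXCLUDED_FROM_TESTING,
)
from .nutrition_profiling import case_nutrition, loss_table, nutrition_table
from .guideline_compliance import BASES, check_menu, compliance_table
from .carbon_footprint import case_emissions, emissions_table
from .economic_impact import case_costs, cost_table
from .comparative_stats import compare_cases, comparison_table

log = logging.getLogger("platewaste")

_MACRO_COMPONENTS = COMPONENTS[:7]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def compute_results(campaign: Campaign) -> dict:
    """Run every stage on a loaded campaign; returns tables plus a summary dict."""
    timings: dict[str, float] = {}

    def _timed(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = time.perf_counter() - self.t0

        return _Ctx()

    with _timed("waste"):
        accounts = build_day_accounts(campaign)
        summaries = {
            case_id: aggregate_case(
                [a for a in accounts if a.case_id == case_id], case_id
            )
            for case_id in campaign.case_ids
            if any(a.case_id == case_id for a in accounts)
        }
    for case_id, s in summaries.items():
        log.info(
            "%s: %d days, served %.1f kg, waste %.1f kg (%.1f %%)",
            case_id, s.n_days, s.total_served_kg, s.total_waste_kg, s.total_waste_pct,
        )
        for flag in s.flags:
            log.warning("%s: data-quality flag raised: %s", case_id, flag)

    with _timed("nutrition"):
        menus = {
            case_id: case_nutrition(campaign, accounts, case_id) for case_id in summaries
        }
    with _timed("compliance"):
        compliance = [
            check_menu(menu, campaign.guidelines, basis)
            for case_id in summaries
            for menu in menus[case_id]
            for basis in BASES
        ]
    with _timed("carbon"):
        emissions = {
            case_id: case_emissions(campaign, accounts, case_id) for case_id in summaries
        }
    with _timed("economics"):
        costs = {case_id: case_costs(campaign, accounts, case_id) for case_id in summaries}

    with _timed("compare"):
        comparisons = _compare_stage(summaries, menus)

    tables = {
        "table1_waste_masses": waste_table(list(summaries.values())),
        "table2_waste_percentages": waste_percentage_table(list(summaries.values())),
        "table3_macronutrients": pd.concat(
            [
                nutrition_table(m)[
                    nutrition_table(m)["component"].isin(_MACRO_COMPONENTS)
                ]
                for m in menus.values()
            ],
            ignore_index=True,
        )
        if menus
        else nutrition_table([]),
        "table4_micronutrients": pd.concat(
            [
                nutrition_table(m)[
                    ~nutrition_table(m)["component"].isin(_MACRO_COMPONENTS)
                ]
                for m in menus.values()
            ],
            ignore_index=True,
        )
        if menus
        else nutrition_table([]),
        "fig1_losses": pd.concat(
            [loss_table(m) for m in menus.values()], ignore_index=True
        )
        if menus
        else loss_table([]),
        "compliance": compliance_table(compliance),
        "table5_emissions": emissions_table(list(emissions.values())),
        "table6_costs": cost_table(list(costs.values())),
        "comparisons": comparison_table(comparisons),
    }

    summary = {
        "version": __version__,
        "cases": {
            case_id: {
                "n_days": s.n_days,
                "total_served_kg": s.total_served_kg,
                "total_waste_kg": s.total_waste_kg,
                "total_waste_pct": s.total_waste_pct,
                "waste_production_kgco2e": emissions[case_id].production_kgco2e,
                "waste_total_kgco2e": emissions[case_id].total_kgco2e,
                "waste_share_of_supply_pct": emissions[case_id].waste_share_of_supply_pct,
                "waste_share_all_components_pct": (
                    emissions[case_id].waste_share_all_components_pct
                ),
                "waste_cost_eur": costs[case_id].total_cost_eur,
                "cost_metrics": costs[case_id].metrics,
                "flags": list(s.flags),
            }
            for case_id, s in summaries.items()
        },
    }
    return {"tables": tables, "summary": summary, "accounts": accounts,
            "timings": timings}


def _compare_stage(summaries, menus) -> list:
    """Between-case comparisons when exactly two cases are present."""
    if len(summaries) != 2:
        return []
    (id_a, s_a), (id_b, s_b) = sorted(summaries.items())
    results = []
    for cat in [*CATEGORY_CODES, "total"]:
        for column in ("waste_pct", "waste_per_child_g"):
            x = s_a.daily_series(cat, column)
            y = s_b.daily_series(cat, column)
            name = f"{cat}:{column}"
            excluded = (name,) if cat in EXCLUDED_FROM_TESTING else ()
            if x.size == 0 or y.size == 0:
                continue
            results.append(compare_cases(x, y, name, excluded=excluded))
    menus_a, menus_b = menus[id_a], menus[id_b]
    for component in _MACRO_COMPONENTS:
        for basis in ("served", "wasted", "intake"):
            x = [getattr(m, basis)[component] for m in menus_a]
            y = [getattr(m, basis)[component] for m in menus_b]
            results.append(compare_cases(x, y, f"{component}:{basis}"))
    for component in COMPONENTS:
        x = [m.loss_pct[component] for m in menus_a]
        y = [m.loss_pct[component] for m in menus_b]
        if any(pd.isna(x)) or any(pd.isna(y)):
            continue
        results.append(compare_cases(x, y, f"{component}:loss_pct"))
    return results


def run_pipeline(data_dir: str | Path, out_dir: str | Path,
                 log_level: str = "INFO") -> dict:
    """Load a campaign directory, run all stages, write tables + manifest.

    Returns the manifest dict.  Any stage error propagates after being logged;
    partial outputs stay on disk but are not listed in a manifest.
    """
    data_dir, out_dir = Path(data_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(log_level.upper())
    try:
        t0 = time.perf_counter()
        campaign = load_campaign(data_dir)
        results = compute_results(campaign)
        table_dir = out_dir / "tables"
        written = write_report_tables(results["tables"], table_dir)
        results_path = out_dir / "results.json"
        results_path.write_text(
            json.dumps(results["summary"], indent=2, sort_keys=True, allow_nan=True),
            encoding="utf-8",
        )
        written.append(results_path)
        manifest = {
            "version": __version__,
            "inputs": {
                p.name: _digest(p) for p in sorted(data_dir.iterdir()) if p.is_file()
            },
            "config_digest": _digest(data_dir / "config.yaml"),
            "outputs": {str(p.relative_to(out_dir)): _digest(p) for p in sorted(written)},
            "stage_timings_s": results["timings"],
            "total_runtime_s": time.perf_counter() - t0,
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
        log.info("pipeline complete: %d output files", len(written))
        return manifest
    except Exception:
        log.exception("pipeline failed; partial outputs in %s are not manifested", out_dir)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
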