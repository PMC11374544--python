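# platewaste

Plate-waste accounting for school-meal campaigns. Starting from aggregate
selective weighings (per-category waste bins pooled over all children), the
pipeline quantifies:

- **mass**: served amounts, waste percentages, waste and intake per child,
  per food category and in total, per day and aggregated;
- **nutrition**: energy and 22 macro/micronutrient components of served,
  wasted and consumed lunches, and percentage losses;
- **guideline compliance**: per-menu-day verdicts against configurable
  school-lunch bounds (closed intervals), as served and as consumed;
- **carbon footprint**: production + transport + disposal emissions embodied
  in the waste, per kg, per serving, and as a share of the supplied-food
  footprint;
- **economic cost**: volume-weighted mean prices per category, waste cost
  totals, daily/per-kg/per-meal metrics and budget shares;
- **statistics**: a normality-gated two-group protocol (Lilliefors-corrected
  Kolmogorov–Smirnov screen, then pooled-variance Student t or Mann–Whitney U
  with an exact small-sample null), with matching mean±SD / median(IQR)
  descriptives.

A synthetic-data module generates complete two-case campaigns (dish library,
recipes, composition, factor/price/guideline tables, Beta-distributed daily
waste fractions) with planted, analytically known ground truth, so every
stage runs and is testable without any external data. The bundled
composition/factor/price/guideline tables are illustrative toy values, not
normative constants.

## CLI

```sh
# generate a two-case campaign (20 + 19 collection days, ~24 % vs ~42 %
# planted total waste) into a campaign directory
platewaste simulate --preset paperlike --seed 1 --out campaign/

# run the full pipeline: tables/, results.json, run.log, manifest.json
platewaste run --data campaign/ --out results/

# or run any stage standalone on the same directory layout
platewaste waste      --data campaign/ --out results/
platewaste nutrition  --data campaign/ --out results/
platewaste compliance --data campaign/ --out results/
platewaste carbon     --data campaign/ --out results/
platewaste economics  --data campaign/ --out results/
platewaste compare    --data campaign/ --out results/
platewaste report     --data campaign/ --out results/
```

A campaign directory holds plain CSV/YAML inputs (`observations.csv`,
`menus.csv`, `dishes.csv`, `recipes.csv`, `composition.csv`, `factors.csv`,
`prices.csv`, `guidelines.csv`, `config.yaml`); the schemas are documented in
`platewaste.data_io`. Replace the generated files with real campaign data to
analyse it with the same commands. Runs are deterministic given the inputs
and seed; `manifest.json` records input/output digests.

## Layout

```
src/platewaste/
  data_io.py             file schemas, domain types, validation, writers
  waste_accounting.py    served/waste/intake mass accounting
  nutrition_profiling.py nutrient content of served/wasted/consumed menus
  guideline_compliance.py bound checks and compliance shares
  carbon_footprint.py    emission accounting (production/transport/disposal)
  economic_impact.py     cost allocation and derived cost metrics
  comparative_stats.py   gated two-group protocol, exact Mann–Whitney U
  synthetic_data.py      campaign generator with planted ground truth
  pipeline.py, cli.py    orchestration and command-line entry points
tests/                   unit, property and acceptance suites
scripts/acceptance.py    acceptance-target report
```
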