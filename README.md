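# nomoscan

Measurement-equivalence statistics for pairs of short trait inventories.

Given two instruments ("methods") that claim to measure the same set of
latent traits, `nomoscan` answers two questions:

1. **Do the instruments converge and discriminate?** A trait-by-method
   confirmatory factor model is fitted to the polychoric correlation matrix
   of the ordinal items by diagonally weighted least squares (DWLS), and
   convergent/discriminant validity is scored with AVE, ordinal alpha, the
   Fornell–Larcker criterion, HTMT ratios (arithmetic or geometric
   denominator), and nested chi-square tests of models in which a
   cross-method factor correlation is constrained to 1.00.
2. **Do they predict the same things?** A three-step consistency analysis
   compares the two methods' trait–criterion correlation profiles: mean
   absolute correlation differences (Δr̄, Fisher-z or raw scale),
   differences of mean regression R² (ΔR̄²), double-entry profile
   intraclass correlations, pairwise Fisher z-tests, and agreement between
   Zellner–Siow (JZS) Bayes-factor evidence categories for
   omitted-predictor regressions. All metrics are screened against fixed
   benchmarks (Δr̄ ≤ .10, ΔR̄² ≤ .05, ICC ≥ .80, p ≥ .05, agreement ≥ 80%).

A seeded synthetic-data generator produces ordinal Likert datasets with a
known trait-by-method factor structure and criterion network (including a
deliberately method-divergent variant), so every estimator can be validated
by parameter recovery. Bundled fixture tables of published regression
summaries and Bayes factors allow the derived consistency statistics to be
reproduced exactly without raw data.

## Command-line usage

```sh
# generate a synthetic dataset (data.csv + codebook.yaml + ground_truth.json)
nomoscan simulate --preset paper --n 504 --seed 42 --out out/sim
# optionally: --divergent for a method-inconsistent variant

# fit the trait-by-method CFA and validity table
nomoscan mtmm --data out/sim/data.csv --codebook out/sim/codebook.yaml \
    --out out/mtmm

# full pipeline: descriptives -> correlations -> CFA -> regressions ->
# Bayes factors -> consistency benchmarks
nomoscan run --data out/sim/data.csv --codebook out/sim/codebook.yaml \
    --seed 1 --out out/report        # add --no-cfa to skip the slow stage

# consistency statistics recomputed from the bundled fixture tables
nomoscan consistency --fixtures paper --out out/fixtures
```

Reports are written as `report.json` (full precision, stable key order)
plus human-readable TSV tables.

## Package layout

| module | contents |
| --- | --- |
| `nomoscan.synthetic` | model spec + seeded generator (latent scores, Likert discretization, criterion scores) |
| `nomoscan.corr` | descriptives, Cronbach/ordinal alpha, Pearson & polychoric correlations, Fisher z, standardized OLS from correlation input |
| `nomoscan.mtmm` | DWLS CFA, fit indices, AVE, HTMT, Fornell–Larcker, nested model comparison |
| `nomoscan.bayesfactor` | JZS BF10 by deterministic quadrature, omitted-predictor BF01, evidence categories |
| `nomoscan.consistency` | Δr̄, ΔR̄², profile ICC, Fisher z-tests, agreement %, benchmark report |
| `nomoscan.pipeline` | codebook/dataset IO, fixture tables, orchestration, serialization |
| `nomoscan.cli` | `nomoscan` entry point |
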