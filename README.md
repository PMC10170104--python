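# metabextract

Evaluation pipeline for comparing sample-extraction methods in untargeted
LC-HRMS metabolomics, built around peak-picked feature tables. Six extraction
groups (`I`, `II`, `III`, `IV`, `III_B`, `IV_B` — the `_B` suffix marks added
bead homogenization) are compared against reference extraction `I`:

- **feature_io** — CSV feature tables (peak areas + feature/sample metadata),
  a compound registry of internal standards and "molecules of interest"
  (MoInt), and JSON pathway sets; strict structural validation. Missing areas
  are empty CSV fields, never zero.
- **synthetic_data** — a generator for feature tables with known ground truth:
  log-normal baselines, multiplicative injection-order drift, pooled-QC
  injections, group-specific fold/CV effects, detection-limit censoring.
- **qc_correction** — per-feature drift correction from repeated pooled-QC
  injections (LOWESS on log areas, linear fallback, identity fallback).
- **univariate_stats** — one-way ANOVA, Welch's t test, Bonferroni
  adjustment, significance categories, detected-feature counting.
- **targeted_eval** — ppm/RT compound matching, normalization to the
  reference extraction's mean area, mean/SD/CV summaries and Welch contrasts.
- **pcdfa** — ANOVA-gated feature selection, centered PCA with
  Kaiser-criterion component retention (minimum two), Fisher discriminant
  axes, Monte Carlo cross-validation with accuracy and Cohen's κ.
- **pathway_enrichment** — hypergeometric over-representation plus
  topology impact from relative betweenness centrality.
- **report** — per-method scorecards (feature count, MoInt recovery, CV) as
  an ordinal arrow matrix, and the umbrella pipeline.

A registry fixture (34 positive-mode MoInt, 16 negative-mode MoInt, 9
internal standards across three spike solutions) and a small pathway set are
bundled under `metabextract.data`.

## CLI

```sh
metabextract simulate --seed 1 --out-prefix scratch/sim        # synthetic table
metabextract correct  --areas sim.areas.csv --samples sim.samples.csv --out-prefix scratch/corr
metabextract stats    --areas ... --samples ... --out stats.csv
metabextract targeted --areas ... --samples ... --out-prefix targ   # bundled registry
metabextract pcdfa    --areas ... --samples ... --iters 1000 --seed 1 --out-prefix pcdfa
metabextract pathways --query kegg_ids.txt --out pathways.csv
metabextract run      --simulate --seed 1 --out-dir results    # full pipeline
```

`simulate` accepts a YAML config (`--config`) mirroring
`metabextract.synthetic_data.SimulationConfig`; without one, the built-in
six-group scenario is used.

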