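# osintegrate

Integration of differential expression, somatic mutation, drug-screen and
pathway evidence for phenotypically extreme ("aggressive" vs "curable") tumor
cohorts, with a synthetic-data generator that provides ground truth for every
stage.

## What it does

- **`osintegrate.simulate`** — synthetic cohorts: negative-binomial counts
  with group effects (variance = μ + φμ²), impact-annotated mutation tables,
  GMT pathway collections with a spiked driver pathway, compound × kinase
  inhibition matrices, and 4PL dose–response data (4 concentrations ×
  3 replicates), all reproducible from one seed.
- **`osintegrate.diffexpr`** — exact negative-binomial tests between two
  phenotype groups under both a common and a per-gene (tagwise) dispersion
  estimate. A gene is significant only when both analyses survive
  Benjamini–Hochberg adjustment at α; if nothing passes, the whole run falls
  back to unadjusted p < α (recorded per run). Also: median-of-ratios library
  normalization and log2(CPM+1) transcriptome Pearson correlation.
- **`osintegrate.mutations`** — gene-level aggregation of variant records by
  impact class (high > moderate > low > modifier), aggressive/curable Venn
  set algebra, and gene-family clustering.
- **`osintegrate.drugscreen`** — multi-start 4PL dose–response fits with
  "> Cmax" censoring, efficacy calls (IC50 < 1 µM, R² > 0.6), median-effect
  fits and Chou–Talalay combination indices (synergy at CI ≤ 0.7), and
  hypergeometric kinase-target deconvolution of effective compounds.
- **`osintegrate.integrate`** — hypergeometric over-representation of
  mutated ∪ differentially expressed genes per pathway, filtered to pathways
  with unadjusted p < 0.05 that contain at least one target of an effective
  compound, plus per-gene node annotations (drug target / mutated /
  de_over / de_under / aberrant) with mutation multiplicity and CNV
  direction.
- **`osintegrate.io` / `osintegrate.pipeline` / `osintegrate.cli`** —
  TSV/CSV/GMT/JSON readers and writers, a manifest-writing pipeline runner,
  and the `osintegrate` command.

## CLI

```sh
# full synthetic pipeline (simulate -> de -> mutations -> screen -> integrate)
osintegrate all --outdir out --seed 7

# individual stages
osintegrate simulate --outdir sim --seed 7 [--config cfg.yaml]
osintegrate de --counts sim/counts.tsv --groups sim/groups.tsv --out de.tsv
osintegrate mutations --table sim/mutations.tsv --phenotypes pheno.tsv \
    --min-impact moderate --mode all --outdir mut
osintegrate screen fit --doseresponse sim/dose_response.csv --out fits.tsv
osintegrate screen deconv --fits fits.tsv --targets sim/compound_targets.tsv \
    --out scores.tsv
osintegrate screen ci --doseresponse dr.csv --compound1 A --compound2 B \
    --culture C --d1 30 --d2 50 --fa 0.5
osintegrate integrate --gmt sim/pathways.gmt --de de.tsv \
    --mutations sim/mutations.tsv --targets sim/compound_targets.tsv \
    --fits fits.tsv --specimen AGG01 --outdir integ
```

`osintegrate all` writes every stage output plus `manifest.json` (input
hashes, parameters, version, seed). Identical config + seed gives
byte-identical outputs.

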