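# phenomet

Phenomics–metabolomics integration toolkit for characterising the mode of
action of plant biostimulants in controlled salt-stress screens.

The package covers the full analysis chain for a two-crop screen
(untreated control + 7 substances × control/salt conditions):

- **`phenomet.synth`** — synthetic data generator: logistic shoot-growth
  phenotyping time series with a late-phase salt penalty, fluorescence
  primitives at four actinic light steps, canopy/chamber temperatures, and
  a low-rank treatment-structured lognormal metabolite block with tunable
  trait coupling. Ground-truth effect labels are kept for recovery tests.
- **`phenomet.traits`** — trait derivation: digital biomass (volume proxy
  from top/side projected areas), relative growth rate, light-adapted
  quantum yields (Fv′/Fm′, ΦPSII), NPQ, canopy temperature depression (δT),
  water-use efficiency; per-plant, per-phase (early = day 0–12, late =
  12–21/24) trait tables plus ANOVA + Tukey HSD group comparison.
- **`phenomet.pbc`** — the biostimulant characterisation index: the sum of
  five log2(treated/control) trait ratios per substance × condition ×
  phase, with promoter/inhibitor/alleviator classification.
- **`phenomet.multivariate`** — Ward hierarchical clustering
  (Lance–Williams on euclidean / squared-euclidean / manhattan
  dissimilarities), the 75 %-presence compound filter, and OPLS-DA with
  VIP ranking, stratified-CV Q2Y, label-permutation testing and a
  CV-ANOVA F-test.
- **`phenomet.differential`** — volcano filtering (per-compound ANOVA with
  Bonferroni correction combined with a two-sided fold-change threshold)
  and per-category cumulative fold-change aggregation.
- **`phenomet.integrate`** — random-forest trait importance (held-out
  permutation importance), trait–metabolite Pearson correlation, and
  co-inertia analysis with Escoufier's RV coefficient plus a row-permutation
  test.
- **`phenomet.pipeline_io`** — CSV/YAML formats, run configuration and the
  orchestrated end-to-end pipeline with per-stage persisted outputs and a
  provenance block.

## CLI

```sh
phenomet simulate --crop lettuce --seed 1 --out data/
phenomet traits --in data/phenotyping.csv --crop lettuce --out traits.csv
phenomet pbc --traits traits.csv --out pbc/ --plot
phenomet mva opls --in data/abundance.csv --meta data/samples.csv --ortho 1 --perm 200 --out mva/
phenomet volcano --in data/abundance.csv --meta data/samples.csv \
    --contrast H_control_vs_CTRL_control --out volcano.csv
phenomet integrate --traits traits.csv --abundance data/abundance.csv \
    --meta data/samples.csv --out integrate/
phenomet run --pheno data/phenotyping.csv --abundance data/abundance.csv \
    --meta data/samples.csv --categories data/categories.csv --seed 1 --out run/
```

`phenomet run` executes traits → PBC → HCA → OPLS-DA (+ validation) →
volcano → random forest → correlation → co-inertia, writing every stage's
CSV/YAML output before the next stage starts; reruns with identical
config + inputs + seed are byte-identical.

## File formats

- Phenotyping CSV: one row per plant × phenotyping day; required columns
  are listed in `phenomet.pipeline_io.PHENO_REQUIRED_COLUMNS`.
- Feature table: abundance CSV (samples × compounds, blank = missing, never
  zero), sample metadata CSV (`sample_id, substance, condition, replicate`),
  optional category map CSV (`compound_id, category`).
- Run configuration: YAML, schema = `phenomet.pipeline_io.RunConfig`.
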