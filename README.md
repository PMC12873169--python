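# microstab

Longitudinal microbiome stability toolkit. Given genus-level
relative-abundance tables with per-sample metadata (individual, age group
I/A/E, collection day, subject age), it computes:

- **Core microbiota** — per-group taxon prevalence at a detection limit
  (default: abundance strictly above 1e-4), cores at 100/80/50%
  prevalence thresholds, and the 7-region membership partition across the
  three age groups. Prevalence is per *sample* pooled within a group, so
  individuals with more samples carry more weight.
- **Temporal similarity** — within-individual Jaccard similarity of
  presence sets as a function of time gap (60-day bins), and the
  *Jaccard core index* `|C∩S| / (|C| + |S| − |C∩S|)` of each sample
  against a fixed 50%-prevalence reference core, tracked against subject
  age.
- **Taylor's-law stability** — per-individual OLS fit of
  `log10 σ = β·log10 μ + const` over taxa, giving the power-law index β
  (½ ≈ Poisson-like, 1 ≈ exponential-like) and fluctuation amplitude
  `V = 10^(2·intercept)` so that `σ² = V·μ^(2β)`; standardization of
  (log10 V, β) to the Adult reference group and a circular
  "healthy window" at the 68%/98% levels (`r = sqrt(−2 ln(1−p))`).
- **Taxa-function robustness** — projection of compositions into function
  space through a genome-content table (16S-copy-number corrected),
  random taxon-knockout perturbations, a hinge fit
  `d_F = s·max(0, d_T − b)` of functional vs taxonomic Bray-Curtis
  shifts, and null standardization against shuffled genome-row
  assignments yielding *attenuation* and *buffering* scores, globally and
  per pathway/superpathway. The hinge + row-shuffle construction is a
  fully specified stand-in for external robustness pipelines, not a
  re-implementation of any of them.
- **Group statistics** — two-sided Wilcoxon rank-sum comparisons (exact
  null for small tie-free samples, normal approximation with continuity
  and tie corrections otherwise) and Benjamini-Hochberg adjustment.
- **Synthetic cohorts** — a seeded generator producing three-age-group
  longitudinal cohorts whose per-taxon fluctuations honor the designed
  Taylor law (with a moment-exact noiseless mode for estimator oracles),
  a core/transient prevalence structure with an age trend, and
  genome-content bundles with a tunable functional-redundancy knob.

## CLI

Global flags come before the subcommand:

```sh
microstab --seed 1 --out results/sim simulate
microstab --out results/core core --abundance results/sim/abundance.tsv \
    --metadata results/sim/metadata.tsv --thresholds 1.0,0.8,0.5
microstab --out results/jac jaccard --abundance results/sim/abundance.tsv \
    --metadata results/sim/metadata.tsv --bin-width 60
microstab --out results/tay taylor --abundance results/sim/abundance.tsv \
    --metadata results/sim/metadata.tsv --reference-group A
microstab --seed 1 --out results/rob robustness \
    --abundance results/sim/abundance.tsv --metadata results/sim/metadata.tsv \
    --content results/sim/genome_content.tsv --rrn results/sim/rrn.tsv \
    --pathways results/sim/pathway_map.tsv --level superpathway
microstab --out results/cmp compare --input results/jac/jaccard_core_index.tsv \
    --metric jci --group-col sample_group --adjust bh
microstab --seed 1 --out results/all all      # simulate + every stage
```

All tables are TSV (floats at 10 significant digits, so written tables
re-read bit-exactly); each run writes a `manifest.json` with the config,
seed, and library versions, and re-running with the same seed reproduces
every output bit-identically. A JSON config (`--config`) can override any
simulator knob (`{"cohort": {...}, "genome": {...}}`).

## Layout

| module | contents |
| --- | --- |
| `microstab.data` | sample/table/threshold/pathway-map types, TSV+JSON I/O, validation |
| `microstab.simulate` | cohort and genome-content generators |
| `microstab.core` | prevalence profiles, core sets, cross-group partition |
| `microstab.temporal` | Jaccard pairs, 60-day binning, Jaccard core index |
| `microstab.taylor` | moments, power-law fits, standardization, healthy window |
| `microstab.robustness` | functional projection, perturbation, hinge fit, null scores |
| `microstab.stats` | rank-sum comparisons, BH adjustment |
| `microstab.cli` | `simulate` / `core` / `jaccard` / `taylor` / `robustness` / `compare` / `all` |
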