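# gwaselect

A tested, reusable pipeline for ordinal-trait GWAS and downstream population
genetics on simulated cohorts: genotype QC → additive association scan →
trans-ethnic meta-analysis with heterogeneity → Bayes-factor credible-set
fine-mapping → three families of positive-selection tests (haplotype-based
iHS, pairwise selection-coefficient differences on logit allele frequencies,
and polygenic-score divergence against a multivariate-normal drift null).
A forward Wright–Fisher simulator with selection, population splits and an
ordinal (3-level, multi-rater) phenotype generator provides truth-tagged
inputs for every stage.

## Modules

| module | what it does |
|---|---|
| `gwaselect.io_formats` | phased-VCF read/write, summary-stat/covariate TSVs, genetic maps, QC filtering (missingness, MAF, exact HWE, INFO), greedy LD pruning, YAML config, run manifests |
| `gwaselect.synthetic_data` | forward Wright–Fisher simulation (drift, recombination, mutation, selection with dominance, splits, burn-in, single-origin sweeps) and latent-trait → ordinal phenotype generation with rater confusion |
| `gwaselect.gwas_core` | per-variant OLS additive scan with covariates, conditional analysis, genomic-control λ, PCA covariates, per-SNP variance explained |
| `gwaselect.meta_analysis` | allele harmonization, sample-size-weighted and inverse-variance fixed-effects meta, Cochran's Q / I², DerSimonian–Laird random effects |
| `gwaselect.finemap_credible` | approximate Bayes factors, posterior causal probabilities, 99% credible sets per locus |
| `gwaselect.selection_haplotype` | EHH profiles (combinatorial form, 0.05 cutoff), trapezoidal iHH, bin-standardized iHS with Gaussian p and empirical top-0.1% cutoffs |
| `gwaselect.selection_divergence` | logit allele-frequency contrasts with a genome-wide calibrated null, per-frequency-bin scale |
| `gwaselect.polygenic_adaptation` | polygenic scores `Z_m = 2 Σ β_l p_ml` and the excess-divergence (Qx-style) test with chi-square and matched-resampling nulls |
| `gwaselect.phenotype_metrics` | Cohen's kappa, Gini–Simpson diversity, covariate association summaries |
| `gwaselect.pipeline_driver` | end-to-end orchestration over K simulated cohorts with persisted per-stage outputs and a markdown report |

## CLI

Every subcommand takes `--seed`, `--config` (YAML) and `--out`, and writes a
`manifest.json` with parameters and library versions:

```sh
gwaselect simulate  --seed 1 --config config.yaml --out run/sim
gwaselect qc        --seed 1 --out run/qc   --vcf run/sim/A.vcf
gwaselect gwas      --seed 1 --out run/gwas --vcf run/sim/A.vcf --pheno run/sim/A.pheno.tsv
gwaselect meta      --seed 1 --out run/meta --stats run/gwasA/summary.tsv --stats run/gwasB/summary.tsv
gwaselect finemap   --seed 1 --out run/fm   --stats run/meta/meta_stats.tsv --top v00042
gwaselect ihs       --seed 1 --out run/ihs  --vcf run/sim/A.vcf --map map.tsv
gwaselect seldiff   --seed 1 --out run/sd   --freqs freqs.tsv --pop-a A --pop-b B --focal focal.tsv
gwaselect qx        --seed 1 --out run/qx   --scored scored.tsv --freqs freqs.tsv
gwaselect phenostats --seed 1 --out run/ps  --pheno run/sim/A.pheno.tsv
gwaselect pipeline  --seed 1 --config config.yaml --out run/full
```

An example YAML config:

```yaml
simulation:
  n_diploid: {C1: 2000, C2: 2000, C3: 2000}
  n_sites: 100
  sequence_length: 4000000
  recombination_rate: 1.0e-8
  generations: 40
  split_generation: 20
trait:
  causal: [[v00025, 0.4], [v00075, 0.4]]
  noise_sd: 1.0
  n_raters: 3
```

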