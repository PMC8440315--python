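# gsel

Genomic selection toolkit for identifying promising donor accessions from a
genotyped gene-bank panel. It implements:

- **Genotype handling** — VCF / dosage-TSV readers, marker filtering
  (missingness > 5% or MAF < 2.5% removed by default), mean-dosage
  imputation, and the VanRaden genomic relationship matrix (no shrinkage).
- **GBLUP core** — exact single-component REML (spectral, EMMA-style
  one-dimensional profile of the variance ratio), BLUP prediction of
  genotypic values for tested *and* untested accessions, per-environment
  phenotype standardisation for multi-environment fits, and broad-sense
  heritability `H2 = Vg / (Vg + Ve/R)` from replicated trials.
- **Selection criteria** — predicted genotypic value (PGV) ranking and
  expected improvement `EI = (m - M) Φ(z) + s φ(z)` over the best observed
  accession, with prediction SDs from either the mixed-model-equation
  conditional covariance or a Gibbs sampler on the Bayesian GBLUP
  (default schedule 6000 iterations, 1200 burn-in, thinning 5 → 960 draws).
  Top-k selection with deterministic tie-breaks, overlap accounting across
  criteria/sites/traits, and equally-spaced control sets.
- **Evaluation protocols** — repeated tenfold cross-validation (accessions,
  not records, are partitioned), forward validation split into repeated vs
  new accessions, and phenotypic / genetic correlation matrices across
  site-year environments.
- **Synthetic data** — genotype pools under Hardy–Weinberg sampling and
  multi-environment replicated phenotypes with known marker effects,
  configurable heritability and cross-environment genetic correlation.
  The trait architecture (Gaussian effects at a random QTL subset,
  independent markers) is a stand-in chosen for testability, not an estimate
  of any real panel.

## Command line

The `gs` entry point exposes each stage and an end-to-end runner:

```sh
gs simulate --config config.yaml --out sim/
gs filter --genotypes sim/genotypes.vcf --format vcf --out filtered.tsv
gs grm --genotypes filtered.tsv --out grm.tsv
gs fit --grm grm.tsv --phenotypes sim/phenotypes.csv --trait trait --out fit.tsv
gs run-all --config config.yaml --out run/
```

A minimal simulation-mode config:

```yaml
simulation:
  n_pool: 1000
  n_train: 300
  n_markers: 2000
  n_qtl: 2000
  h2_per_env: {siteA: 0.5}
k: 20
n_controls: 23
run_cv: true
seed: 42
```

`run-all` writes every intermediate artifact (filtered genotypes, GRM, fits,
criteria tables, selections, evaluation reports) plus `manifest.json` with a
config hash and per-file checksums; reruns with the same config are
byte-identical. Multi-cycle configs (`cycles: 2`) re-phenotype the selected
accessions from the simulation truth and refit on the augmented training set.

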