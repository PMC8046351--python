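# vctwas

Variance-component transcriptome-wide association tests.

`vctwas` implements a gene-level association test that weights SNPs by
reference cis-eQTL effect sizes and treats their phenotype effects as
random, with variance proportional to the squared weight.  The score
statistic

```
Q = (Y - mu)' G W G' (Y - mu),   W = diag(w_j^2)
```

follows a mixture of 1-df chi-squares under the null; tail probabilities
are computed by characteristic-function inversion with a saddlepoint route
for the far tail and a flagged moment-matching fallback.  Because only the
squared weights enter, the test is robust to the sign (and partially to the
magnitude) of the eQTL weight estimates — unlike the classical two-stage
"burden" TWAS, which regresses the phenotype on imputed expression
`GReX = G w` and is also provided here as a comparator.

Both tests run from:

* **individual-level data** — genotypes + phenotype + covariates
  (gaussian or binomial phenotypes), or
* **GWAS summary statistics** — per-SNP effect/SE/N plus a reference LD
  covariance matrix, from which single-variant score statistics and the
  phenotype variance are reconstructed.

Also included: elastic-net and shrinkage eQTL weight training with 5-fold
CV R², weight filtering (per-gene median / magnitude threshold), Fisher
meta-analysis across cohorts with Benjamini–Hochberg FDR, and a simulation
harness (LD-structured genotypes, expression and phenotype generators,
power and type-I-error studies).

## CLI

All stages are under one entry point:

```bash
vctwas train-weights --genotypes ref.vcf --expression expr.tsv \
    --method elastic_net --out weights.tsv

vctwas vc-twas --genotypes test.vcf --phenotype pheno.tsv \
    --covariates covars.tsv --family gaussian \
    --weights weights.tsv --weight-filter median --out results.tsv

vctwas vc-twas-ss --gwas gwas.tsv --ld ld.tsv --weights weights.tsv \
    --weight-filter threshold --threshold 1e-4 --out results_ss.tsv

vctwas burden-twas ...      # individual-level burden comparator
vctwas burden-twas-ss ...   # summary-level burden comparator

vctwas simulate --scenario-file scenarios.toml --study power \
    --methods vc:dense,burden:dense --reps 1000 --out sim.tsv

vctwas meta --inputs cohort1.tsv --inputs cohort2.tsv --out meta.tsv
```

File formats are plain TSV throughout: dosage tables
(`CHROM POS REF ALT SNP_ID <samples...>`), weight files
(`CHROM POS REF ALT GENE_ID WEIGHT [CV_R2]`, PrediXcan/TIGAR-compatible,
allele-aware with sign flipping on ref/alt swaps), GWAS summary files
(`CHROM POS REF ALT SNP_ID BETA SE N`), and symmetric LD matrices with a
SNP-id header row.  VCF input (GT or DS fields) is read via cyvcf2.

## Package layout

| module | contents |
| --- | --- |
| `vctwas.genotype_io` | VCF / dosage-table loading, QC (MAF, HWE), LD covariance |
| `vctwas.weights` | weight training (elastic net, ridge, EB dense stand-in), filtering, weight-file IO |
| `vctwas.vc_individual` | null models, Q statistic, null mixture eigenvalues, gene-level test |
| `vctwas.vc_summary` | score/variance reconstruction from summary stats, summary-level test |
| `vctwas.burden` | GReX imputation and burden tests (individual & summary) |
| `vctwas.simulation` | genotype/expression/phenotype generators, type-I and power studies |
| `vctwas.meta_results` | Fisher meta-analysis, BH FDR, result tables |
| `vctwas._quadform` | chi-square-mixture tail probabilities and quantiles |
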