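# exoburden

Exome-wide rare-variant burden analysis of cognitive ability.

## The scientific problem

General cognitive ability (*g*) is highly heritable and positively
associated with fitness components, so selection should deplete its genetic
variance — yet the variance persists. Under a mutation–selection balance,
that variance would be maintained by a steady influx of rare, mostly
deleterious mutations. A direct test of this model is to count, for each
person, the **total number of rare alleles** they carry across
protein-altering exonic variants (stop-gain/loss, splice and missense SNPs
with minor allele frequency ≤ 0.01) and regress cognitive ability on that
count — the additive mutation-load model:

```
cognition_i = β0 + β_age · (age_i − mean age) + β_sex · female_i + β_burden · burden_i + ε_i

burden_i = Σ_j  minor-allele dosage of person i at rare variant j
```

`exoburden` implements this analysis as a tested, reusable pipeline for
exome-genotyping-array data in PLINK binary format, aimed at cohort studies
with cognitive phenotypes measured in childhood (Moray House Test, scored
0–76) and in late life (MHT plus a PCA-derived fluid *g* factor from a test
battery). Because cohort genotype data cannot be redistributed, the package
ships a first-class **synthetic cohort generator** that reproduces the
statistical structure of such a study — rare-skewed MAF spectrum, ~96%
non-synonymous variant content, per-person rare-allele totals near 185
(MAF ≤ 0.01), array error processes (haploid heterozygous calls on the male
X, missing calls, monomorphic sites) and a configurable ground-truth burden
effect — so every downstream stage is testable end to end.

## Pipeline stages

1. **simulate** — synthetic exome-array cohort with known ground truth
   (`exoburden.simulate`).
2. **io** — PLINK .bed/.bim/.fam reader/writer, annotation and phenotype
   TSVs (`exoburden.io_genotype`).
3. **qc** — haploid-het → monomorphic → SNP call rate < 97% → sample call
   rate < 97%, with exact per-stage accounting (`exoburden.qc`).
4. **burden** — in-sample MAF, minor-allele orientation, rare-variant
   selection, additive burden per class set, 4-s.d. outlier rule
   (`exoburden.burden`).
5. **phenotype_g** — standardized first principal component of the
   late-life battery (`exoburden.phenotype_g`).
6. **assoc** — covariate-adjusted OLS, the 2 thresholds × 5 class sets ×
   3 phenotypes sensitivity grid (30 models) and Bonferroni correction
   (`exoburden.assoc`, `exoburden.pipeline`).

## Worked example

Simulate a cohort of 1 000 people at 46 000 variants under the null
(no burden effect) and run the full analysis:

```sh
exoburden simulate --seed 1 --out demo
exoburden run --genotypes demo/cohort \
    --annotation demo/cohort.annotation.tsv \
    --phenotypes demo/cohort.phenotypes.tsv \
    --out demo/results
```

`demo/results/qc_report.tsv` accounts for every QC removal:

```
n_samples_in              1000
n_snps_in                 46000
n_haploid_het_set_missing 1378
n_monomorphic_removed     10985
n_snps_callrate_removed   0
n_samples_callrate_removed 0
n_snps_out                35015
n_samples_out             1000
```

1 378 male-X heterozygous calls (necessarily genotyping errors) were set to
missing, and 10 985 monomorphic variants were dropped, leaving 35 015 SNPs.
`demo/results/descriptives.tsv` summarizes the analysed cohort:

```
measure                    n     mean      sd
childhood_age_years        1000  10.90     0.29
late_life_age_years        1000  78.99     0.61
mht_childhood              1000  47.45     12.02
mht_late_life              1000  57.61     10.69
fluid_g                    1000  0.00      1.00
rare_alleles_maf_le_0.01   1000  176.90    13.19
rare_alleles_maf_le_0.05   1000  503.01    22.61
fraction_female            1000  0.59
```

The fluid *g* factor is standardized to mean 0, variance 1 by construction,
and the rare-allele total at the looser MAF ≤ 0.05 cut-off is necessarily
larger than at MAF ≤ 0.01 (superset of variants). The association grid
(`demo/results/associations.tsv`, 30 rows) reports unstandardized b, s.e.
and p for every term; for the primary model here:

```
phenotype  maf_threshold  class_set        n     b_burden  se_burden  p_burden  p_bonferroni
mht_child  0.01           combined_nonsyn  1000  -0.0241   0.0283     0.395     1
mht_late   0.01           combined_nonsyn  1000  -0.0201   0.0256     0.433     1
g_late     0.01           combined_nonsyn  1000   0.0018   0.0024     0.456     1
```

As expected under a simulated null, no burden coefficient survives the
Bonferroni correction (family size m = 30, the number of models run). A
cohort simulated with `--effect-per-allele -0.05` instead yields burden
coefficients distributed around −0.05 MHT points per rare allele; the test
suite verifies this recovery (and the 5% type-I error rate under the null)
over hundreds of replicate cohorts.

## Limitations

Variants are simulated independently (no linkage disequilibrium,
relatedness or population structure), there is no gene-level collapsing or
SKAT-type variance-component testing, and no gene×gene or gene×environment
terms. See `docs/methods.md` for the model, parameter defaults and
numerical conventions.
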