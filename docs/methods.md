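# Methods

## The burden statistic

For person *i* and a variant selection *S* (a functional class set
intersected with an in-sample MAF cut-off), the global burden is the
unweighted additive sum

    burden_i = Σ_{j ∈ S} d_ij,

where `d_ij` is the minor-allele dosage (0/1/2; on the male X, 0/2,
haploid coded diploid). "Rare" means MAF ≤ 0.01, with MAF ≤ 0.05 as the
sensitivity cut-off; both thresholds are inclusive. MAF is computed
in-sample on the post-QC matrix — no external reference panel — with
haploid males contributing one allele on the X chromosome. The
minor-allele orientation is frozen at MAF-computation time (ties at
f = 0.5 orient to A1); the burden counts minor alleles, not A1 alleles as
stored on disk, because file orientation is not trustworthy.

Missing calls contribute 0 alleles under the default `zero` policy; a
`mean_impute` policy (variant mean minor dosage) is available since the
handling of residual missingness in a hard-call burden is a convention.
Under `zero` the totals are integers bounded by 2·|S|, and per-class
burdens add exactly to the combined burden.

## Quality control

The cascade is a single pass in a fixed order: (1) male-X heterozygous
calls → missing, (2) monomorphic variants removed, (3) variants with call
rate < 97% removed, (4) samples with call rate < 97% removed. Monomorphism
and call rates are judged on the matrix as it stands when the stage runs,
so stage-1 missingness counts against call rates. The threshold is strict
(<): a call rate of exactly 0.97 survives. Monomorphism is judged on
observed calls; an all-missing variant counts as monomorphic and is
removed there. Call rates are not re-evaluated between the variant and
sample filters; on realistic missingness patterns the cascade is
idempotent, and the test suite verifies this on simulated cohorts.
Upstream consortium-style QC (relatedness, heterozygosity, sex checks) is
assumed done before the pipeline and is out of scope.

## Fluid g

The late-life battery (3–6 positively intercorrelated tests) is reduced to
its first principal component: complete-case rows, each test z-scored
(n − 1 divisor), eigendecomposition of the test correlation matrix —
correlation, not covariance, because battery tests have heterogeneous
scales — and scores z-standardized so the output has mean 0, variance 1
exactly. The component sign is flipped when the loading sum is negative,
so higher g always means better performance. A test with zero variance or
fewer than 3 tests/10 complete cases is an error, not a silent drop. No
rotation and no confirmatory factor model.

## Association models

Each model is OLS of one phenotype (childhood MHT, late-life MHT, or
late-life g) on `[1, age − mean(age), sex_female, burden]`, with the age
mean taken on the per-phenotype complete-case subset and sex coded
female = 1. Standard errors are classical (σ̂²(XᵀX)⁻¹, σ̂² = RSS/(n − k));
p-values are two-sided from the t distribution with n − k df. No robust or
mixed-model errors. The default sensitivity grid crosses MAF thresholds
{0.01, 0.05} with class sets {stop+splice+missense, stop-gain/loss,
splice, missense, all including synonymous} and the three phenotypes —
30 models. The Bonferroni family size is the number of models actually
fitted in the invocation (30 by default), overridable, and is always
reported alongside the adjusted p-values. Before any model is fitted, a
single-pass outlier rule removes samples whose combined non-synonymous
burden at the most stringent threshold lies more than 4 s.d. from the mean
(mean and s.d. computed once); the removed ids are logged and excluded
from all 30 models. Model diagnostics are numeric surrogates for
diagnostic plots: residual mean, skew, and the largest absolute
standardized residual, flagged above 4.

## The synthetic cohort generator

The generator emulates a late-life birth-cohort exome-chip study; its
defaults are the package's reference study conditions.

**Genotypes.** True minor-allele frequencies are drawn from a Beta(0.6,
91.1) distribution truncated to (0, 0.5] — rare-skewed, density ∝ p^−0.4
near zero — calibrated jointly with `n_variants = 46000` and
`monomorphic_rate = 0.10` so that (a) ~78% of segregating variants have
MAF ≤ 0.01 and (b) the per-person ground-truth rare-allele total averages
≈ 185 with the default 96% non-synonymous class mix (0.02 stop-gain/loss /
0.02 splice / 0.92 missense / 0.04 synonymous). Genotypes are independent
Binomial(2, p) draws (Hardy–Weinberg); male X calls are haploid draws
coded {0, 2}. Because variants are independent, the burden s.d. is ≈
√mean ≈ 13.5, somewhat below the ~17 seen in real cohorts, where LD and
array design induce positive covariance; the generator deliberately omits
LD, relatedness and population structure, so passing tests speak to the
pipeline's statistics, not to population-genetic realism. Error processes
are injected only after the ground truth is frozen: haploid heterozygous
calls on male-X cells at rate 0.003 (~2.5% of variants are placed on X),
then missing calls at rate 0.002. The delivered-data burden at MAF ≤ 0.01
therefore averages ≈ 177 rather than 185: selecting on the observed
(error-injected, in-sample) frequency slightly favours downward-fluctuating
variants near the threshold, exactly as it would in a real analysis.

**Ground truth.** `true_burdens` is computed on the error-free matrix with
the same rule the burden module applies downstream (in-sample MAF ≤ 0.01,
non-synonymous classes, minor-allele orientation), so with error injection
disabled the pipeline's burden reproduces it exactly (round-trip test),
and with defaults the recovery tests measure only the attenuation the
error processes cause.

**Phenotypes.** MHT scores follow
`mean + β_age(age − mean age) + β_sex·female + β_burden·(burden − mean) +
N(0, σ)`, rounded half-up and clamped to the instrument range [0, 76].
Defaults: childhood mean 46.8, σ 12.0, age 10.9 ± 0.29 y, β_age +8
points/year, β_sex(female) +0.2; late life mean 59.4, σ 11.0, age 79.0 ±
0.58 y, β_age −1.2, β_sex −2.8; 59% female. The burden term is
mean-centred so the configured MHT means stay interpretable; the slope —
the estimand — is unchanged. `effect_per_allele` defaults to 0 (the null).
The latent fluid factor is `effect·(burden − mean)/σ_late + N(0, 1)`,
standardized; each battery test is `loading·g + 0.6·N(0, 1)` on the
standardized scale (default loadings 0.80…0.55 for 6 tests), then mapped
to per-test display scales so correlation-based extraction is actually
exercised. An optional survivor-truncation step drops the lowest
`floor(q·n)` samples on a latent health score `g + N(0, 1)`, emulating the
range restriction of healthy-survivor cohorts; tests verify it shrinks
phenotype s.d.

**Seeding.** One `numpy.random.Generator` seeded from `config.seed` drives
every draw; replicate *k* of a study uses `seed + k`. Identical configs
produce byte-identical output files.

## Numerical conventions and degenerate inputs

- Missing sentinel −1 in an int8 dosage matrix; PLINK v1.00 SNP-major
  2-bit encoding for on-disk genotypes.
- All standardizations use the n − 1 divisor.
- A variant with zero non-missing calls makes MAF undefined and raises
  (QC removes such variants first); an empty rare-variant selection is a
  warning, not an error; an empty matrix after QC raises.
- Rank-deficient designs raise with the collinear column names; models
  with fewer than 10 complete cases raise.

## Verification problem sizes

Statistical guarantees are checked by simulation in the test suite: type-I
error calibration of the burden t-test over 500 null cohorts (n = 500,
5 000 variants; rejection rate within [0.03, 0.07] at α = 0.05), and
recovery of `effect_per_allele = −0.05` over 100 cohorts at n = 1 000
(mean estimate within 2 Monte-Carlo s.e.; 95% CI coverage within
[0.92, 0.98]). Replicate cohorts for these checks use 5 000 variants —
estimator calibration is free of the variant-count scale — while
single-cohort checks run at the full 46 000-variant default. Oracle
equivalence (burden vs a per-cell loop; OLS vs closed-form normal
equations, to 1e-8) is checked on 100 random fixtures each.

## Known limitations

No LD/relatedness/structure in the generator; no VCF or dosage-format
ingestion; no weighting schemes (e.g. frequency-weighted burdens), no
gene-level collapsing, no variance-component (SKAT-type) tests; single
cohort per run (meta-analysis across cohorts is composition by the
caller); the burden s.d. of real arrays is underestimated as noted above.
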