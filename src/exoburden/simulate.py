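"""Synthetic exome-array cohorts with known ground truth.

The generator emulates a birth-cohort exome-chip study: ~1 000 participants
genotyped at tens of thousands of mostly non-synonymous coding variants with
a rare-skewed allele-frequency spectrum, Moray House Test (MHT) scores at
age 11 and in late life bounded on [0, 76], and a positively intercorrelated
late-life cognitive battery with one dominant factor. Genotypes are drawn
independently per variant under Hardy–Weinberg proportions (no linkage
disequilibrium, relatedness or population structure). Error processes of
real array data are injected after the ground truth is frozen: haploid
heterozygous calls on the male X, missing calls, and monomorphic sites.

Ground truth records, per sample, the rare non-synonymous minor-allele
burden of the error-free genotypes, so recovery of a configured per-allele
phenotype effect can be checked exactly downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from .core import (
    MISSING,
    NONSYN_CLASSES,
    SEX_FEMALE,
    SEX_MALE,
    X_CHROM,
    GenotypeMatrix,
    VariantRecord,
)
from .errors import ConfigurationError
from .io_genotype import write_annotation, write_phenotypes, write_plink

MHT_MIN, MHT_MAX = 0, 76

# display scale (offset, sd multiplier) cycled over battery tests so the
# battery exercises correlation-based (not covariance) factor extraction
_BATTERY_SCALES = ((55.0, 12.0), (30.0, 8.0), (14.0, 5.0), (7.5, 2.3), (25.0, 6.0), (11.0, 4.0))

_DEFAULT_LOADINGS = (0.80, 0.75, 0.70, 0.65, 0.60, 0.55)


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Defaults are calibrated to the published cohort descriptives of a
    1921-born Scottish birth cohort: mean rare-allele totals near 186
    (s.d. ~14 under independent variants) at MAF <= 0.01, childhood MHT
    47 +/- 12 at mean age 10.9, late-life MHT 59 +/- 11 at mean age 79,
    59% female, and ~96% non-synonymous variants on the array.
    ``effect_per_allele`` is the signed phenotype change (MHT points) per
    rare non-synonymous allele carried; 0 simulates the null.
    """

    n_samples: int = 1000
    n_variants: int = 46000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "stop_gain_loss": 0.02,
            "splice": 0.02,
            "missense": 0.92,
            "synonymous": 0.04,
        }
    )
    # true minor-allele frequencies: Beta(a, b) truncated to (0, 0.5]
    maf_spectrum: dict[str, Any] = field(
        default_factory=lambda: {"name": "beta", "a": 0.6, "b": 91.1}
    )
    missing_rate: float = 0.002
    haploid_het_rate: float = 0.003
    frac_x_chromosome: float = 0.025
    monomorphic_rate: float = 0.10
    effect_per_allele: float = 0.0
    age_child_mean: float = 10.9
    age_child_sd: float = 0.29
    age_late_mean: float = 79.0
    age_late_sd: float = 0.58
    sex_ratio: float = 0.59  # fraction female
    mht_child_mean: float = 46.8
    mht_child_sd: float = 12.0
    mht_late_mean: float = 59.4
    mht_late_sd: float = 11.0
    age_effect_child: float = 8.0  # MHT points per year at age 11
    age_effect_late: float = -1.2  # cognitive ageing slope
    sex_effect_child: float = 0.2  # female minus male, MHT points
    sex_effect_late: float = -2.8
    battery_size: int = 6
    battery_loadings: tuple[float, ...] | None = None
    noise_sd: float = 0.6  # battery test-specific residual (standardized scale)
    survivor_truncation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_variants <= 0:
            raise ConfigurationError("n_samples and n_variants must be positive")
        tot = sum(self.class_proportions.values())
        if abs(tot - 1.0) > 1e-12:
            raise ConfigurationError(f"class_proportions sum to {tot}, expected 1")
        for name in (
            "missing_rate", "haploid_het_rate", "frac_x_chromosome",
            "monomorphic_rate", "sex_ratio",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not 3 <= self.battery_size <= 6:
            raise ConfigurationError("battery_size must be in 3..6")
        if self.battery_loadings is not None and len(self.battery_loadings) != self.battery_size:
            raise ConfigurationError("battery_loadings length must equal battery_size")
        if self.survivor_truncation is not None and not 0.0 <= self.survivor_truncation < 1.0:
            raise ConfigurationError("survivor_truncation quantile must be in [0, 1)")
        if self.maf_spectrum.get("name") not in ("beta", "uniform"):
            raise ConfigurationError(
                f"unknown maf_spectrum {self.maf_spectrum.get('name')!r}"
            )
        if self.maf_spectrum["name"] == "beta":
            a, b = self.maf_spectrum.get("a", 0), self.maf_spectrum.get("b", 0)
            if a <= 0 or b <= 0:
                raise ConfigurationError("beta spectrum requires a > 0 and b > 0")

    @property
    def loadings(self) -> np.ndarray:
        base = self.battery_loadings or _DEFAULT_LOADINGS[: self.battery_size]
        return np.asarray(base, dtype=np.float64)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["battery_loadings"] = (
            list(self.battery_loadings) if self.battery_loadings else None
        )
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if d.get("battery_loadings"):
            d["battery_loadings"] = tuple(d["battery_loadings"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Error-free quantities frozen before error injection."""

    true_mafs: np.ndarray  # spectrum frequencies, 0 for forced-monomorphic
    true_burdens: np.ndarray  # rare non-synonymous minor-allele sums, error-free
    true_effect: float
    latent_g: np.ndarray | None = None  # filled by the phenotype stage
    rare_nonsyn_idx: np.ndarray | None = None
    n_haploid_het_injected: int = 0  # male-X het calls present in delivered matrix
    n_missing_injected: int = 0


@dataclass
class SimulatedCohort:
    """Bundle of one synthetic cohort: genotypes, phenotypes, ground truth."""

    matrix: GenotypeMatrix
    cohort: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def _draw_mafs(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.maf_spectrum
    n = config.n_variants
    if spec["name"] == "uniform":
        lo, hi = spec.get("low", 0.0), spec.get("high", 0.5)
        if not (0.0 <= lo < hi <= 0.5):
            raise ConfigurationError("uniform spectrum requires 0 <= low < high <= 0.5")
        return rng.uniform(lo, hi, size=n)
    p = rng.beta(spec["a"], spec["b"], size=n)
    # truncate support to (0, 0.5]; beta mass above 0.5 is tiny for rare-skewed defaults
    while (bad := p > 0.5).any():
        p[bad] = rng.beta(spec["a"], spec["b"], size=int(bad.sum()))
    return p


def simulate_variants(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[VariantRecord], np.ndarray]:
    """Draw variant identities, positions, classes and true MAFs.

    Variants are sorted by (chromosome, position) with strictly increasing
    1-based positions within each chromosome; a ``monomorphic_rate`` fraction
    is forced to frequency 0.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_variants

    classes = rng.choice(
        list(config.class_proportions),
        size=n,
        p=list(config.class_proportions.values()),
    )
    mafs = _draw_mafs(config, rng)
    n_mono = int(round(config.monomorphic_rate * n))
    if n_mono:
        mafs[rng.choice(n, size=n_mono, replace=False)] = 0.0

    is_x = rng.random(n) < config.frac_x_chromosome
    chrom = np.where(is_x, X_CHROM, rng.integers(1, 23, size=n).astype(str))
    # strictly increasing positions per chromosome via cumulative gaps
    pos = np.empty(n, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.cumsum(rng.integers(100, 20000, size=idx.size))
    # sort by (chromosome, position), X last
    key = np.array([23 if c == X_CHROM else int(c) for c in chrom])
    order = np.lexsort((pos, key))

    alleles = np.array(["A", "C", "G", "T"])
    a2_idx = rng.integers(0, 4, size=n)
    a1_idx = (a2_idx + rng.integers(1, 4, size=n)) % 4  # any base != A2
    a1, a2 = alleles[a1_idx], alleles[a2_idx]

    records = [
        VariantRecord(
            id=f"var{i:06d}",
            chrom=str(chrom[j]),
            pos=int(pos[j]),
            a1=str(a1[j]),
            a2=str(a2[j]),
            func_class=str(classes[j]),
        )
        for i, j in enumerate(order)
    ]
    return records, mafs[order]


def simulate_genotypes(
    variants: list[VariantRecord],
    true_mafs: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw genotypes under Hardy–Weinberg and inject array error processes.

    Autosomal dosages are Binomial(2, maf); male X dosages are haploid coded
    diploid ({0, 2}). The ground-truth burden is computed on the error-free
    matrix (in-sample minor-allele orientation and MAF <= 0.01, restricted to
    non-synonymous classes) before haploid-het and missing-call injection.
    """
    if len(variants) != len(true_mafs):
        raise ConfigurationError("variants and true MAF vector are not aligned")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, v = config.n_samples, len(variants)

    sex = np.where(rng.random(n) < config.sex_ratio, SEX_FEMALE, SEX_MALE).astype(np.int8)
    dosage = rng.binomial(2, true_mafs[None, :], size=(n, v)).astype(np.int8)

    is_x = np.array([rec.chrom == X_CHROM for rec in variants])
    male_rows = np.flatnonzero(sex == SEX_MALE)
    x_cols = np.flatnonzero(is_x)
    if male_rows.size and x_cols.size:
        hap = rng.binomial(1, true_mafs[x_cols][None, :], size=(male_rows.size, x_cols.size))
        dosage[np.ix_(male_rows, x_cols)] = (2 * hap).astype(np.int8)

    matrix = GenotypeMatrix(
        samples=[f"sample{i:05d}" for i in range(n)],
        variants=variants,
        dosage=dosage,
        sex=sex,
    )

    # freeze ground truth on the clean matrix
    clean_maf, minor_is_a1 = burden_mod.compute_maf(matrix)
    classes = matrix.func_classes()
    rare_nonsyn = np.flatnonzero(
        (clean_maf > 0) & (clean_maf <= 0.01) & np.isin(classes, list(NONSYN_CLASSES))
    )
    true_burdens = burden_mod.compute_burden(matrix, rare_nonsyn, minor_is_a1, "zero")
    for rec in matrix.variants:
        rec.maf = None  # downstream recomputes on the delivered (error-injected) matrix

    # error injection: haploid heterozygous calls, then missing calls
    n_het = 0
    if male_rows.size and x_cols.size and config.haploid_het_rate > 0:
        het_mask = rng.random((male_rows.size, x_cols.size)) < config.haploid_het_rate
        block = dosage[np.ix_(male_rows, x_cols)]
        block[het_mask] = 1
        dosage[np.ix_(male_rows, x_cols)] = block
    miss_mask = rng.random((n, v)) < config.missing_rate
    dosage[miss_mask] = MISSING
    if male_rows.size and x_cols.size:
        n_het = int((dosage[np.ix_(male_rows, x_cols)] == 1).sum())

    truth = GroundTruth(
        true_mafs=np.asarray(true_mafs, dtype=np.float64),
        true_burdens=true_burdens,
        true_effect=config.effect_per_allele,
        rare_nonsyn_idx=rare_nonsyn,
        n_haploid_het_injected=n_het,
        n_missing_injected=int(miss_mask.sum()),
    )
    return matrix, truth


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def simulate_phenotypes(
    matrix: GenotypeMatrix,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate ages, MHT scores and the late-life cognitive battery.

    MHT scores are a linear model in mean-centred age, sex (female) and the
    mean-centred ground-truth burden, plus Gaussian noise, rounded half-up
    and clamped to the instrument range [0, 76]. The latent fluid factor g
    carries the burden effect on the same points-per-allele scale divided by
    the late-life MHT noise s.d., so a burden shifting MHT by one residual
    s.d. shifts g by about one s.d.; battery tests load on g with
    test-specific noise and per-test display scales.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = matrix.n_samples
    female = (matrix.sex == SEX_FEMALE).astype(np.float64)
    burden_c = truth.true_burdens - truth.true_burdens.mean()

    age_child = rng.normal(config.age_child_mean, config.age_child_sd, size=n)
    age_late = rng.normal(config.age_late_mean, config.age_late_sd, size=n)

    def mht(mean, age, age_eff, sex_eff, noise_sd):
        raw = (
            mean
            + age_eff * (age - age.mean())
            + sex_eff * female
            + config.effect_per_allele * burden_c
            + rng.normal(0.0, noise_sd, size=n)
        )
        return np.clip(_round_half_up(raw), MHT_MIN, MHT_MAX)

    mht_child = mht(
        config.mht_child_mean, age_child, config.age_effect_child,
        config.sex_effect_child, config.mht_child_sd,
    )
    mht_late = mht(
        config.mht_late_mean, age_late, config.age_effect_late,
        config.sex_effect_late, config.mht_late_sd,
    )

    g_signal = config.effect_per_allele * burden_c / config.mht_late_sd
    latent_raw = g_signal + rng.normal(0.0, 1.0, size=n)
    latent_g = (latent_raw - latent_raw.mean()) / latent_raw.std(ddof=1)
    truth.latent_g = latent_g

    data = {
        "sample_id": matrix.samples,
        "sex": np.where(female == 1, "F", "M"),
        "age_child": np.round(age_child, 3),
        "age_late": np.round(age_late, 3),
        "mht_child": mht_child.astype(int),
        "mht_late": mht_late.astype(int),
    }
    loadings = config.loadings
    for j in range(config.battery_size):
        offset, scale = _BATTERY_SCALES[j % len(_BATTERY_SCALES)]
        std_score = loadings[j] * latent_g + config.noise_sd * rng.normal(size=n)
        data[f"battery_{j + 1}"] = np.round(offset + scale * std_score, 3)
    cohort = pd.DataFrame(data)
    cohort["sex_female"] = female.astype(int)
    return cohort


def apply_survivor_selection(
    cohort: pd.DataFrame,
    truncation_quantile: float,
    latent_g: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop the least-healthy fraction of the cohort (survivor bias).

    A latent health score ``latent_g + N(0, 1)`` links survival positively to
    cognition; the lowest ``floor(q * n)`` samples are removed, emulating the
    range restriction of a healthy-survivor study. Returns the truncated
    cohort and the boolean keep mask (for aligning genotypes/ground truth).
    """
    if not 0.0 <= truncation_quantile < 1.0:
        raise ConfigurationError("truncation quantile must be in [0, 1)")
    n = len(cohort)
    if truncation_quantile == 0.0:
        return cohort, np.ones(n, dtype=bool)
    rng = rng if rng is not None else np.random.default_rng(0)
    health = latent_g + rng.normal(size=n)
    n_drop = int(np.floor(truncation_quantile * n))
    drop_idx = np.argsort(health)[:n_drop]
    keep = np.ones(n, dtype=bool)
    keep[drop_idx] = False
    return cohort.loc[keep].reset_index(drop=True), keep


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Run the full generator from one seed: variants, genotypes, phenotypes.

    A single :class:`numpy.random.Generator` seeded with ``config.seed``
    drives every draw; replicate k of a study should use ``seed + k``.
    """
    rng = np.random.default_rng(config.seed)
    variants, true_mafs = simulate_variants(config, rng)
    matrix, truth = simulate_genotypes(variants, true_mafs, config, rng)
    cohort = simulate_phenotypes(matrix, truth, config, rng)
    if config.survivor_truncation:
        cohort, keep = apply_survivor_selection(
            cohort, config.survivor_truncation, truth.latent_g, rng
        )
        matrix = matrix.subset(sample_idx=np.flatnonzero(keep))
        truth.true_burdens = truth.true_burdens[keep]
        truth.latent_g = truth.latent_g[keep]
    return SimulatedCohort(matrix=matrix, cohort=cohort, truth=truth, config=config)


def write_cohort(sim: SimulatedCohort, outdir: str | Path, prefix: str = "cohort") -> dict[str, Path]:
    """Write PLINK trio, annotation, phenotype and ground-truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = outdir / prefix
    write_plink(sim.matrix, stem)
    write_annotation(sim.matrix, stem.with_suffix(".annotation.tsv"))
    write_phenotypes(sim.cohort, stem.with_suffix(".phenotypes.tsv"))
    truth_df = pd.DataFrame(
        {
            "sample_id": sim.matrix.samples,
            "true_burden": sim.truth.true_burdens.astype(int),
            "latent_g": np.round(sim.truth.latent_g, 6),
        }
    )
    truth_df.to_csv(stem.with_suffix(".ground_truth.tsv"), sep="\t", index=False)
    return {
        "bed": stem.with_suffix(".bed"),
        "bim": stem.with_suffix(".bim"),
        "fam": stem.with_suffix(".fam"),
        "annotation": stem.with_suffix(".annotation.tsv"),
        "phenotypes": stem.with_suffix(".phenotypes.tsv"),
        "ground_truth": stem.with_suffix(".ground_truth.tsv"),
    }
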