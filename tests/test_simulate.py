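"""Cohort generator: spectrum, genotype sampling, phenotypes, truncation."""

import numpy as np
import pytest

from exoburden.core import MISSING, SEX_MALE, X_CHROM
from exoburden.errors import ConfigurationError
from exoburden.simulate import (
    SimulationConfig,
    apply_survivor_selection,
    simulate_cohort,
    simulate_genotypes,
    simulate_phenotypes,
    simulate_variants,
)


class TestSimulateVariants:
    def test_degenerate_proportions_all_missense(self):
        cfg = SimulationConfig(
            seed=0, n_variants=10,
            class_proportions={"stop_gain_loss": 0.0, "splice": 0.0,
                               "missense": 1.0, "synonymous": 0.0},
        )
        variants, _ = simulate_variants(cfg)
        assert len(variants) == 10
        assert all(v.func_class == "missense" for v in variants)

    def test_forced_monomorphic(self):
        cfg = SimulationConfig(seed=0, n_variants=50, monomorphic_rate=1.0)
        _, mafs = simulate_variants(cfg)
        assert (mafs == 0).all()

    def test_class_fractions_converge(self):
        """50 000 draws: empirical class fractions within 1% of the target."""
        cfg = SimulationConfig(seed=1, n_variants=50000)
        variants, _ = simulate_variants(cfg)
        classes = np.array([v.func_class for v in variants])
        for cls, p in cfg.class_proportions.items():
            assert abs((classes == cls).mean() - p) < 0.01

    def test_positions_strictly_increasing_per_chromosome(self):
        cfg = SimulationConfig(seed=3, n_variants=2000)
        variants, _ = simulate_variants(cfg)
        by_chrom: dict[str, list[int]] = {}
        for v in variants:
            by_chrom.setdefault(v.chrom, []).append(v.pos)
        for chrom, pos in by_chrom.items():
            assert all(a < b for a, b in zip(pos, pos[1:])), chrom
        assert all(p[0] >= 1 for p in by_chrom.values())

    def test_rare_fraction_near_calibration(self):
        """Default spectrum: ~78% of segregating variants have MAF <= 0.01."""
        cfg = SimulationConfig(seed=2, n_variants=30000)
        _, mafs = simulate_variants(cfg)
        seg = mafs[mafs > 0]
        assert abs((seg <= 0.01).mean() - 0.78) < 0.02
        assert (seg <= 0.5).all()


class TestSimulateGenotypes:
    def test_zero_maf_gives_reference_or_missing(self):
        cfg = SimulationConfig(seed=0, n_samples=50, n_variants=20,
                               monomorphic_rate=1.0)
        variants, mafs = simulate_variants(cfg)
        matrix, _ = simulate_genotypes(variants, mafs, cfg)
        assert np.isin(matrix.dosage, (0, MISSING)).all()

    def test_full_missingness(self):
        cfg = SimulationConfig(seed=0, n_samples=20, n_variants=10, missing_rate=1.0)
        variants, mafs = simulate_variants(cfg)
        matrix, _ = simulate_genotypes(variants, mafs, cfg)
        assert (matrix.dosage == MISSING).all()

    def test_allele_frequency_within_binomial_se(self):
        """1 000 samples at one autosomal variant with maf 0.25: the observed
        frequency falls within 3 binomial standard errors."""
        cfg = SimulationConfig(
            seed=7, n_samples=1000, n_variants=1, missing_rate=0.0,
            haploid_het_rate=0.0, monomorphic_rate=0.0, frac_x_chromosome=0.0,
            maf_spectrum={"name": "uniform", "low": 0.25, "high": 0.2500001},
        )
        variants, mafs = simulate_variants(cfg)
        matrix, _ = simulate_genotypes(variants, mafs, cfg)
        f = matrix.dosage.mean() / 2
        se = np.sqrt(0.25 * 0.75 / (2 * 1000))
        assert abs(f - 0.25) < 3 * se

    def test_male_x_calls_are_homozygous_coded(self):
        cfg = SimulationConfig(seed=4, n_samples=200, n_variants=500,
                               frac_x_chromosome=0.2, haploid_het_rate=0.0,
                               missing_rate=0.0)
        variants, mafs = simulate_variants(cfg)
        matrix, truth = simulate_genotypes(variants, mafs, cfg)
        male_x = matrix.dosage[np.ix_(matrix.is_male, matrix.is_x)]
        assert np.isin(male_x, (0, 2)).all()
        assert truth.n_haploid_het_injected == 0

    def test_haploid_het_bookkeeping(self):
        cfg = SimulationConfig(seed=4, n_samples=200, n_variants=500,
                               frac_x_chromosome=0.2, haploid_het_rate=0.1,
                               missing_rate=0.0)
        variants, mafs = simulate_variants(cfg)
        matrix, truth = simulate_genotypes(variants, mafs, cfg)
        male_x = matrix.dosage[np.ix_(matrix.is_male, matrix.is_x)]
        assert (male_x == 1).sum() == truth.n_haploid_het_injected > 0


class TestSimulatePhenotypes:
    def test_mht_bounds_hold(self):
        for seed in (0, 1):
            sim = simulate_cohort(SimulationConfig(seed=seed, n_samples=300,
                                                   n_variants=2000))
            for col in ("mht_child", "mht_late"):
                assert sim.cohort[col].between(0, 76).all()

    def test_null_effect_uncorrelated(self):
        """effect_per_allele = 0: burden-phenotype correlation near zero."""
        sim = simulate_cohort(
            SimulationConfig(seed=3, n_samples=2000, n_variants=3000,
                             effect_per_allele=0.0)
        )
        r = np.corrcoef(sim.truth.true_burdens, sim.cohort["mht_child"])[0, 1]
        assert abs(r) < 0.05

    def test_marginal_calibration(self):
        """Default config lands near the target cohort descriptives."""
        sim = simulate_cohort(SimulationConfig(seed=8))
        c = sim.cohort
        assert c["mht_child"].mean() == pytest.approx(46.8, abs=1.5)
        assert c["age_child"].mean() == pytest.approx(10.9, abs=0.05)
        assert c["age_late"].mean() == pytest.approx(79.0, abs=0.1)
        assert c["sex_female"].mean() == pytest.approx(0.59, abs=0.05)
        assert sim.truth.true_burdens.mean() == pytest.approx(185.9, rel=0.03)

    def test_battery_positively_intercorrelated(self, small_sim):
        corr = small_sim.cohort[[f"battery_{j}" for j in range(1, 7)]].corr()
        off = corr.to_numpy()[~np.eye(6, dtype=bool)]
        assert (off > 0.05).all()

    def test_latent_g_carries_burden_effect(self):
        sim = simulate_cohort(
            SimulationConfig(seed=6, n_samples=2000, n_variants=3000,
                             effect_per_allele=-0.3)
        )
        r = np.corrcoef(sim.truth.true_burdens, sim.truth.latent_g)[0, 1]
        assert r < -0.05


class TestSurvivorSelection:
    def test_zero_quantile_is_identity(self, small_sim):
        out, keep = apply_survivor_selection(
            small_sim.cohort, 0.0, small_sim.truth.latent_g
        )
        assert keep.all() and len(out) == len(small_sim.cohort)

    def test_retained_count_forced(self, small_sim):
        rng = np.random.default_rng(11)
        n = len(small_sim.cohort)
        out, _ = apply_survivor_selection(
            small_sim.cohort, 0.5, small_sim.truth.latent_g, rng
        )
        assert len(out) == int(np.ceil(0.5 * n))

    def test_truncation_shrinks_phenotype_sd(self):
        cfg = SimulationConfig(seed=12, n_samples=2000, n_variants=2000)
        sim = simulate_cohort(cfg)
        rng = np.random.default_rng(12)
        out, _ = apply_survivor_selection(sim.cohort, 0.5, sim.truth.latent_g, rng)
        # battery tests load on the health-linked latent factor
        assert out["battery_1"].std(ddof=1) < sim.cohort["battery_1"].std(ddof=1)

    def test_invalid_quantile_raises(self, small_sim):
        with pytest.raises(ConfigurationError):
            apply_survivor_selection(small_sim.cohort, 1.0, small_sim.truth.latent_g)


class TestConfigAndDeterminism:
    def test_invalid_configs_raise(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_samples=0)
        with pytest.raises(ConfigurationError):
            SimulationConfig(class_proportions={"missense": 0.5, "splice": 0.4,
                                                "stop_gain_loss": 0.0,
                                                "synonymous": 0.0})
        with pytest.raises(ConfigurationError):
            SimulationConfig(missing_rate=1.5)
        with pytest.raises(ConfigurationError):
            SimulationConfig(maf_spectrum={"name": "beta", "a": -1, "b": 2})
        with pytest.raises(ConfigurationError):
            SimulationConfig(maf_spectrum={"name": "zipf"})

    def test_same_seed_reproduces(self):
        cfg = SimulationConfig(seed=42, n_samples=100, n_variants=800)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        assert np.array_equal(a.matrix.dosage, b.matrix.dosage)
        assert a.cohort.equals(b.cohort)
        assert np.array_equal(a.truth.true_burdens, b.truth.true_burdens)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_samples=77, effect_per_allele=-0.05)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimulationConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg
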