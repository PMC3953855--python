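"""Shared fixtures: hand-built genotype matrices and small simulated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from exoburden.core import GenotypeMatrix, VariantRecord, SEX_FEMALE, SEX_MALE
from exoburden.simulate import SimulationConfig, simulate_cohort


def make_matrix(
    dosage,
    chroms: list[str] | None = None,
    sex: list[int] | None = None,
    classes: list[str] | None = None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage list-of-lists."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, v = dosage.shape
    chroms = chroms or ["1"] * v
    classes = classes or ["missense"] * v
    sex = sex if sex is not None else [SEX_FEMALE] * n
    variants = [
        VariantRecord(
            id=f"v{j}", chrom=chroms[j], pos=100 * (j + 1), a1="A", a2="G",
            func_class=classes[j],
        )
        for j in range(v)
    ]
    return GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        variants=variants,
        dosage=dosage,
        sex=np.asarray(sex, dtype=np.int8),
    )


def random_matrix(rng: np.random.Generator, n: int = 50, v: int = 200) -> GenotypeMatrix:
    """Random matrix with missing calls, X variants and mixed sexes/classes."""
    dosage = rng.integers(0, 3, size=(n, v)).astype(np.int8)
    dosage[rng.random((n, v)) < 0.05] = -1
    chroms = ["X" if rng.random() < 0.1 else str(rng.integers(1, 23)) for _ in range(v)]
    classes = [
        str(rng.choice(["stop_gain_loss", "splice", "missense", "synonymous", "other"]))
        for _ in range(v)
    ]
    sex = rng.choice([SEX_MALE, SEX_FEMALE], size=n)
    m = make_matrix(dosage, chroms=chroms, sex=list(sex), classes=classes)
    # male X calls must be homozygous-coded (haploid); keep hets only as errors
    for j, c in enumerate(chroms):
        if c == "X":
            male = m.is_male
            col = m.dosage[male, j]
            col[col == 1] = 2
            m.dosage[male, j] = col
    return m


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated cohort reused by read-only tests."""
    cfg = SimulationConfig(seed=11, n_samples=400, n_variants=6000)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
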