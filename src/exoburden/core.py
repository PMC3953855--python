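"""In-memory data model: variant records and the genotype dosage matrix.

Dosages count copies of the A1 allele and take values ``{0, 1, 2, MISSING}``.
Male X-chromosome genotypes are haploid but stored diploid-coded, i.e. a
correct call is 0 or 2; a male X dosage of 1 is a haploid heterozygous
genotyping error. ``MISSING`` is the sentinel ``-1`` in an ``int8`` array.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Missing-call sentinel in the dosage matrix.
MISSING: int = -1

#: Closed set of functional variant classes.
FUNC_CLASSES = ("stop_gain_loss", "splice", "missense", "synonymous", "other")

#: Classes the field treats as non-synonymous (protein/transcript altering).
NONSYN_CLASSES = ("stop_gain_loss", "splice", "missense")

#: Sex codes in the per-sample sex vector.
SEX_MALE, SEX_FEMALE, SEX_UNKNOWN = 0, 1, -1

X_CHROM = "X"


@dataclass
class VariantRecord:
    """A single exome-array variant.

    Parameters
    ----------
    id : str
        Variant identifier (e.g. ``var000123``).
    chrom : str
        Chromosome label, ``"1"``–``"22"`` or ``"X"``.
    pos : int
        1-based physical position.
    a1, a2 : str
        Allele strings; A1 is the counted allele of the dosage matrix.
    func_class : str
        One of :data:`FUNC_CLASSES`.
    maf : float or None
        In-sample minor allele frequency; ``None`` until computed.
    """

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    func_class: str = "other"
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: position must be >= 1, got {self.pos}")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(
                f"variant {self.id}: unknown functional class {self.func_class!r}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x variants allele-dosage matrix with per-sample sex.

    ``dosage[i, j]`` counts A1 alleles of sample ``i`` at variant ``j`` and is
    one of ``{0, 1, 2, MISSING}``. Sex is coded ``SEX_FEMALE = 1``,
    ``SEX_MALE = 0``, ``SEX_UNKNOWN = -1``.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        n, v = self.dosage.shape
        if n != len(self.samples) or v != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.sex.shape != (n,):
            raise ValueError("sex vector length must equal number of samples")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chrom_of(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def is_x(self) -> np.ndarray:
        """Boolean mask of X-chromosome variants."""
        return np.array([v.chrom == X_CHROM for v in self.variants])

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == SEX_MALE

    @property
    def is_female(self) -> np.ndarray:
        return self.sex == SEX_FEMALE

    def func_classes(self) -> np.ndarray:
        return np.array([v.func_class for v in self.variants])

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given sample/variant indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            variants=[replace(self.variants[j]) for j in vi],
            dosage=self.dosage[np.ix_(si, vi)].copy(),
            sex=self.sex[si].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset()
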