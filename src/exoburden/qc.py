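"""Second-stage genotype quality control.

The cascade runs once, in a fixed order:

1. haploid heterozygous calls (male X dosage 1) set to missing,
2. monomorphic variants removed,
3. variants with call rate < 97% removed,
4. samples with call rate < 97% removed.

Call rates and monomorphism are judged on the matrix as it stands when the
stage runs, so missingness created in stage 1 counts against call rates.
Thresholds are strict: a call rate of exactly 0.97 is kept. The cascade is a
single pass — rates are not re-evaluated after the variant filter — and is
idempotent: a second run removes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .core import MISSING, SEX_UNKNOWN, GenotypeMatrix
from .errors import QCError

logger = logging.getLogger(__name__)

DEFAULT_CALLRATE = 0.97


@dataclass
class QCReport:
    """Per-stage accounting of the QC cascade."""

    n_samples_in: int
    n_snps_in: int
    n_haploid_het_set_missing: int
    n_monomorphic_removed: int
    n_snps_callrate_removed: int
    n_samples_callrate_removed: int
    n_snps_out: int
    n_samples_out: int
    snp_callrate_threshold: float = DEFAULT_CALLRATE
    sample_callrate_threshold: float = DEFAULT_CALLRATE

    def __post_init__(self) -> None:
        assert self.n_snps_out == (
            self.n_snps_in - self.n_monomorphic_removed - self.n_snps_callrate_removed
        ), "SNP accounting identity violated"
        assert self.n_samples_out == (
            self.n_samples_in - self.n_samples_callrate_removed
        ), "sample accounting identity violated"

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("field\tvalue\n")
            for k, v in asdict(self).items():
                fh.write(f"{k}\t{v}\n")


def set_haploid_het_missing(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Set male X-chromosome heterozygous calls to missing.

    These are necessarily genotyping errors: a male is haploid on X, so a
    heterozygous call cannot be real. Autosomes are untouched.
    """
    is_x = matrix.is_x
    if not is_x.any():
        return matrix, 0
    if (matrix.sex == SEX_UNKNOWN).any():
        raise QCError("X-chromosome variants present but some samples have unknown sex")
    out = matrix.copy()
    cell = np.ix_(np.flatnonzero(out.is_male), np.flatnonzero(is_x))
    het = out.dosage[cell] == 1
    count = int(het.sum())
    block = out.dosage[cell]
    block[het] = MISSING
    out.dosage[cell] = block
    logger.info("haploid heterozygous calls set to missing: %d", count)
    return out, count


def remove_monomorphic(matrix: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Remove variants showing a single allele among observed calls.

    A variant is monomorphic when its non-missing dosages carry only A1
    alleles, only A2 alleles, or when every call is missing.
    """
    dos = matrix.dosage
    called = dos != MISSING
    n_called = called.sum(axis=0)
    a1_count = np.where(called, dos, 0).sum(axis=0)
    mono = (a1_count == 0) | (a1_count == 2 * n_called)  # covers all-missing too
    count = int(mono.sum())
    out = matrix.subset(variant_idx=np.flatnonzero(~mono)) if count else matrix
    logger.info("monomorphic variants removed: %d", count)
    return out, count


def filter_variant_callrate(
    matrix: GenotypeMatrix, threshold: float = DEFAULT_CALLRATE
) -> tuple[GenotypeMatrix, int]:
    """Remove variants whose call rate is strictly below the threshold."""
    callrate = (matrix.dosage != MISSING).mean(axis=0)
    drop = callrate < threshold
    count = int(drop.sum())
    out = matrix.subset(variant_idx=np.flatnonzero(~drop)) if count else matrix
    logger.info("variants removed at call rate < %g: %d", threshold, count)
    return out, count


def filter_sample_callrate(
    matrix: GenotypeMatrix, threshold: float = DEFAULT_CALLRATE
) -> tuple[GenotypeMatrix, int]:
    """Remove samples whose call rate is strictly below the threshold."""
    if matrix.n_variants == 0:
        raise QCError("no variants left; cannot compute sample call rates")
    callrate = (matrix.dosage != MISSING).mean(axis=1)
    drop = callrate < threshold
    count = int(drop.sum())
    out = matrix.subset(sample_idx=np.flatnonzero(~drop)) if count else matrix
    if out.n_samples == 0:
        raise QCError("all samples removed by call-rate filter")
    logger.info("samples removed at call rate < %g: %d", threshold, count)
    return out, count


def run_qc(
    matrix: GenotypeMatrix,
    snp_callrate: float = DEFAULT_CALLRATE,
    sample_callrate: float = DEFAULT_CALLRATE,
) -> tuple[GenotypeMatrix, QCReport]:
    """Run the four-stage cascade once and return the filtered matrix + report."""
    n_samples_in, n_snps_in = matrix.n_samples, matrix.n_variants
    matrix, n_het = set_haploid_het_missing(matrix)
    matrix, n_mono = remove_monomorphic(matrix)
    matrix, n_snp_cr = filter_variant_callrate(matrix, snp_callrate)
    matrix, n_sample_cr = filter_sample_callrate(matrix, sample_callrate)
    report = QCReport(
        n_samples_in=n_samples_in,
        n_snps_in=n_snps_in,
        n_haploid_het_set_missing=n_het,
        n_monomorphic_removed=n_mono,
        n_snps_callrate_removed=n_snp_cr,
        n_samples_callrate_removed=n_sample_cr,
        n_snps_out=matrix.n_variants,
        n_samples_out=matrix.n_samples,
        snp_callrate_threshold=snp_callrate,
        sample_callrate_threshold=sample_callrate,
    )
    return matrix, report
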