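"""Per-individual rare-allele burden scores.

The burden statistic is the additive mutation-load model: for each person,
the total count of minor alleles carried across a selected set of rare
variants (in-sample MAF at or below a threshold, restricted to a functional
class set). No weighting and no gene-level collapsing — the statistic is the
unweighted exome-wide sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, NONSYN_CLASSES, GenotypeMatrix
from .errors import AnalysisError

logger = logging.getLogger(__name__)

#: Class sets of the sensitivity grid, in report order.
CLASS_SETS: dict[str, tuple[str, ...]] = {
    "combined_nonsyn": NONSYN_CLASSES,
    "stop_gain_loss": ("stop_gain_loss",),
    "splice": ("splice",),
    "missense": ("missense",),
    "all_incl_synonymous": NONSYN_CLASSES + ("synonymous",),
}


@dataclass
class BurdenResult:
    """Burden totals for one (MAF threshold, class set) cell."""

    totals: np.ndarray
    sample_ids: list[str]
    n_variants_used: int
    maf_threshold: float
    class_set: tuple[str, ...]
    missing_policy: str = "zero"
    outliers_removed: list[str] = field(default_factory=list)


def allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """A1 allele frequency per variant over non-missing calls.

    On the X chromosome males are haploid: a male contributes one allele
    (dosage/2) and a female two, so the denominator is
    ``2 * n_female_called + n_male_called``. Autosomes use ``2 * n_called``.

    Raises
    ------
    AnalysisError
        If a variant has zero non-missing calls (QC should have removed it).
    """
    dos = matrix.dosage
    called = dos != MISSING
    if not called.any(axis=0).all():
        j = int(np.flatnonzero(~called.any(axis=0))[0])
        raise AnalysisError(
            f"variant {matrix.variants[j].id} has no non-missing calls; MAF undefined"
        )
    counts = np.where(called, dos, 0).astype(np.float64)

    alleles = np.where(called, 2.0, 0.0)
    is_x = matrix.is_x
    if is_x.any():
        male = matrix.is_male
        # haploid males: one allele, dosage/2 counted copies
        counts[np.ix_(male, np.flatnonzero(is_x))] /= 2.0
        alleles[np.ix_(male, np.flatnonzero(is_x))] /= 2.0
    return counts.sum(axis=0) / alleles.sum(axis=0)


def compute_maf(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Compute per-variant MAF and freeze the minor-allele orientation.

    Returns ``(maf, minor_is_a1)`` where ``maf = min(f, 1 - f)`` for the A1
    frequency ``f``, and ``minor_is_a1`` records which allele the burden sum
    counts. A tie at f = 0.5 orients to A1. The MAF is also stored on each
    :class:`~exoburden.core.VariantRecord`.
    """
    f = allele_frequency(matrix)
    minor_is_a1 = f <= 0.5
    maf = np.where(minor_is_a1, f, 1.0 - f)
    for v, m in zip(matrix.variants, maf):
        v.maf = float(m)
    return maf, minor_is_a1


def minor_dosage(matrix: GenotypeMatrix, minor_is_a1: np.ndarray) -> np.ndarray:
    """Minor-allele dosage matrix (float, NaN for missing calls)."""
    dos = matrix.dosage.astype(np.float64)
    dos[matrix.dosage == MISSING] = np.nan
    flip = ~np.asarray(minor_is_a1)
    dos[:, flip] = 2.0 - dos[:, flip]
    return dos


def select_rare_variants(
    matrix: GenotypeMatrix,
    maf: np.ndarray,
    maf_threshold: float,
    class_set: tuple[str, ...] | frozenset[str],
) -> np.ndarray:
    """Indices of variants with ``0 < MAF <= threshold`` and class in the set.

    The threshold is inclusive; monomorphic (MAF = 0) variants never qualify.
    An empty selection logs a warning but is not an error.
    """
    classes = matrix.func_classes()
    in_class = np.isin(classes, list(class_set))
    idx = np.flatnonzero((maf > 0) & (maf <= maf_threshold) & in_class)
    if idx.size == 0:
        logger.warning(
            "no variants with MAF <= %g in classes %s", maf_threshold, sorted(class_set)
        )
    return idx


def compute_burden(
    matrix: GenotypeMatrix,
    selection: np.ndarray,
    minor_is_a1: np.ndarray,
    missing_policy: str = "zero",
) -> np.ndarray:
    """Per-sample sum of minor-allele dosages over the selected variants.

    ``missing_policy`` is ``"zero"`` (a missing call contributes no alleles)
    or ``"mean_impute"`` (a missing call contributes the variant's mean minor
    dosage over called samples).
    """
    if missing_policy not in ("zero", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    selection = np.asarray(selection)
    if selection.size == 0:
        return np.zeros(matrix.n_samples)
    md = minor_dosage(matrix, minor_is_a1)[:, selection]
    if missing_policy == "zero":
        return np.nansum(md, axis=1)
    col_mean = np.nanmean(md, axis=0)
    filled = np.where(np.isnan(md), col_mean[None, :], md)
    return filled.sum(axis=1)


def remove_burden_outliers(
    burdens: np.ndarray, sample_ids: list[str], n_sd: float = 4.0
) -> tuple[list[str], list[str]]:
    """Single-pass extreme-outlier rule: drop samples beyond ``n_sd`` s.d.

    Mean and s.d. are computed once on all samples (no re-iteration).
    Returns (kept ids, removed ids).
    """
    burdens = np.asarray(burdens, dtype=np.float64)
    if burdens.size < 10:
        raise AnalysisError("outlier rule requires at least 10 samples")
    mu, sd = burdens.mean(), burdens.std(ddof=1)
    if sd == 0 or not np.isfinite(n_sd):
        keep = np.ones(burdens.size, dtype=bool)
    else:
        keep = np.abs(burdens - mu) <= n_sd * sd
    kept = [s for s, k in zip(sample_ids, keep) if k]
    removed = [s for s, k in zip(sample_ids, keep) if not k]
    if removed:
        logger.info("burden outlier rule (%.1f s.d.): removed %d sample(s)", n_sd, len(removed))
    return kept, removed


def burden_result(
    matrix: GenotypeMatrix,
    maf: np.ndarray,
    minor_is_a1: np.ndarray,
    maf_threshold: float,
    class_set_name: str,
    missing_policy: str = "zero",
) -> BurdenResult:
    """Convenience wrapper: select variants and score one grid cell."""
    class_set = CLASS_SETS[class_set_name]
    sel = select_rare_variants(matrix, maf, maf_threshold, class_set)
    totals = compute_burden(matrix, sel, minor_is_a1, missing_policy)
    return BurdenResult(
        totals=totals,
        sample_ids=list(matrix.samples),
        n_variants_used=int(sel.size),
        maf_threshold=maf_threshold,
        class_set=class_set,
        missing_policy=missing_policy,
    )
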