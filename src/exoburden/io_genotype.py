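"""Read/write PLINK binary trios, annotation and phenotype tables.

The binary genotype format is PLINK 1 (v1.00 magic number ``6C 1B 01``,
SNP-major): each variant is stored as ``ceil(n_samples / 4)`` bytes, two bits
per sample starting at the least significant pair, with codes

====  ==========================  ==================
bits  PLINK meaning               A1 dosage
====  ==========================  ==================
00    homozygous A1               2
01    missing                     MISSING
10    heterozygous                1
11    homozygous A2               0
====  ==========================  ==================
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    FUNC_CLASSES,
    MISSING,
    SEX_FEMALE,
    SEX_MALE,
    SEX_UNKNOWN,
    GenotypeMatrix,
    VariantRecord,
)
from .errors import FormatError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

PLINK_MAGIC = bytes((0x6C, 0x1B, 0x01))

# 2-bit PLINK code -> A1 dosage, and its inverse.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

MHT_MIN, MHT_MAX = 0, 76

PHENOTYPE_REQUIRED = ("sample_id", "sex", "age_child", "age_late", "mht_child", "mht_late")


def write_plink(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam for a genotype matrix.

    The .bim file has columns chrom, id, cM (0), pos, A1, A2; the .fam sex
    column uses the PLINK convention 1 = male, 2 = female, 0 = unknown.
    """
    prefix = Path(prefix)
    n = matrix.n_samples

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.a1}\t{v.a2}\n")

    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid, sex in zip(matrix.samples, matrix.sex):
            plink_sex = {SEX_MALE: 1, SEX_FEMALE: 2}.get(int(sex), 0)
            fh.write(f"{sid}\t{sid}\t0\t0\t{plink_sex}\t-9\n")

    # variant-major 2-bit packing, 4 samples per byte, LSB pair first
    codes = np.empty((matrix.n_variants, n), dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[matrix.dosage.T == dos] = code
    n_bytes = (n + 3) // 4
    padded = np.zeros((matrix.n_variants, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(packed.tobytes())


def read_plink(
    bed_path: str | Path, bim_path: str | Path, fam_path: str | Path
) -> GenotypeMatrix:
    """Read a PLINK binary trio into a :class:`GenotypeMatrix`.

    Dosages count A1 alleles; the PLINK missing code maps to :data:`MISSING`.
    Functional classes are ``other`` until an annotation table is applied.

    Raises
    ------
    FormatError
        On a bad magic number or when the .bed payload size does not match
        the .bim/.fam line counts.
    """
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, v = len(fam), len(bim)

    raw = Path(bed_path).read_bytes()
    if raw[:3] != PLINK_MAGIC:
        raise FormatError(f"{bed_path}: not a PLINK v1.00 SNP-major .bed file (bad magic number)")
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != v * n_bytes:
        raise FormatError(
            f"{bed_path}: payload is {payload.size} bytes but .bim/.fam imply "
            f"{v} variants x {n_bytes} bytes"
        )

    packed = payload.reshape(v, n_bytes)
    codes = np.empty((v, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = packed & 0b11
    codes[:, 1::4] = (packed >> 2) & 0b11
    codes[:, 2::4] = (packed >> 4) & 0b11
    codes[:, 3::4] = (packed >> 6) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T

    sex = np.full(n, SEX_UNKNOWN, dtype=np.int8)
    sex[fam["sex"].to_numpy() == 1] = SEX_MALE
    sex[fam["sex"].to_numpy() == 2] = SEX_FEMALE

    variants = [
        VariantRecord(id=r.id, chrom=r.chrom, pos=int(r.pos), a1=r.a1, a2=r.a2)
        for r in bim.itertuples()
    ]
    return GenotypeMatrix(
        samples=fam["iid"].tolist(), variants=variants, dosage=dosage, sex=sex
    )


def read_annotation(tsv_path: str | Path) -> dict[str, str]:
    """Read a two-column variant annotation table (variant_id, class).

    Class strings outside the closed set map to ``other`` with a warning.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    for col in ("variant_id", "class"):
        if col not in df.columns:
            raise SchemaError(f"{tsv_path}: missing required column {col!r}")
    mapping: dict[str, str] = {}
    unknown: set[str] = set()
    for vid, cls in zip(df["variant_id"], df["class"]):
        if cls not in FUNC_CLASSES:
            unknown.add(cls)
            cls = "other"
        mapping[vid] = cls
    if unknown:
        logger.warning(
            "annotation %s: %d unknown class label(s) mapped to 'other': %s",
            tsv_path, len(unknown), sorted(unknown),
        )
    return mapping


def apply_annotation(matrix: GenotypeMatrix, mapping: dict[str, str]) -> int:
    """Assign functional classes in place; unannotated variants become ``other``.

    Returns the number of variants that had no annotation row.
    """
    n_unannotated = 0
    for v in matrix.variants:
        cls = mapping.get(v.id)
        if cls is None:
            n_unannotated += 1
            cls = "other"
        v.func_class = cls
    if n_unannotated:
        logger.warning("%d variant(s) lack annotation; classed 'other'", n_unannotated)
    return n_unannotated


def write_annotation(matrix: GenotypeMatrix, tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("variant_id\tclass\n")
        for v in matrix.variants:
            fh.write(f"{v.id}\t{v.func_class}\n")


def read_phenotypes(tsv_path: str | Path) -> pd.DataFrame:
    """Read the phenotype table (sample_id, sex, ages, MHT scores, battery).

    ``.`` denotes a missing value. Moray House Test scores outside the
    instrument range [0, 76] raise a :class:`ValidationError`; sex is coded
    F/M in the file and returned as a ``sex_female`` 0/1 indicator.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype={"sample_id": str}, na_values=["."])
    for col in PHENOTYPE_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"{tsv_path}: missing required column {col!r}")
    for col in ("mht_child", "mht_late"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.dropna()[(vals.dropna() < MHT_MIN) | (vals.dropna() > MHT_MAX)]
        if len(bad):
            raise ValidationError(
                f"{tsv_path}: {col} value {bad.iloc[0]} outside [{MHT_MIN}, {MHT_MAX}]"
            )
        df[col] = vals
    df["sex_female"] = df["sex"].map({"F": 1, "M": 0})
    return df


def write_phenotypes(cohort: pd.DataFrame, tsv_path: str | Path) -> None:
    out = cohort.drop(columns=[c for c in ("sex_female",) if c in cohort.columns])
    out.to_csv(tsv_path, sep="\t", index=False, na_rep=".")


def align_cohort(
    matrix: GenotypeMatrix, phenotypes: pd.DataFrame
) -> tuple[GenotypeMatrix, pd.DataFrame, int]:
    """Intersect genotype samples with phenotype rows on sample id.

    Sample order follows the genotype matrix. Returns the subset matrix, the
    aligned phenotype frame, and the number of samples dropped from either
    side (logged, mirroring cohort attrition from missing data).
    """
    pheno_ids = set(phenotypes["sample_id"])
    keep_idx = [i for i, s in enumerate(matrix.samples) if s in pheno_ids]
    n_dropped = (matrix.n_samples - len(keep_idx)) + (len(pheno_ids) - len(keep_idx))
    sub = matrix.subset(sample_idx=keep_idx) if len(keep_idx) < matrix.n_samples else matrix
    aligned = (
        phenotypes.set_index("sample_id").loc[sub.samples].reset_index()
    )
    if n_dropped:
        logger.info("sample alignment dropped %d unmatched sample(s)", n_dropped)
    return sub, aligned, n_dropped
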