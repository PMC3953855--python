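"""End-to-end orchestration: QC -> burden -> fluid g -> association grid.

`run_pipeline` ties the stages together on in-memory objects and writes the
report files (QC accounting, burden tables per MAF threshold, g scores and
loadings, the association grid, and a cohort-descriptives table in the shape
of a study Table 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from . import burden as burden_mod
from . import phenotype_g as g_mod
from . import qc as qc_mod
from .core import GenotypeMatrix
from .io_genotype import align_cohort
from .qc import QCReport

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Everything the all-in-one run produces, in memory."""

    matrix: GenotypeMatrix
    qc_report: QCReport
    burden_tables: dict[float, pd.DataFrame]
    g_result: g_mod.GFactorResult
    associations: list[assoc_mod.AssociationResult]
    association_table: pd.DataFrame
    descriptives: pd.DataFrame
    outputs: dict[str, Path] = field(default_factory=dict)


def burden_table(
    matrix: GenotypeMatrix,
    maf: np.ndarray,
    minor_is_a1: np.ndarray,
    maf_threshold: float,
    missing_policy: str = "zero",
) -> pd.DataFrame:
    """Per-sample burden totals for every class set at one MAF threshold."""
    cols = {"sample_id": list(matrix.samples)}
    for name in burden_mod.CLASS_SETS:
        br = burden_mod.burden_result(
            matrix, maf, minor_is_a1, maf_threshold, name, missing_policy
        )
        cols[f"burden_{name}"] = br.totals
    return pd.DataFrame(cols)


def descriptives_table(
    cohort: pd.DataFrame,
    burden_tables: dict[float, pd.DataFrame],
    g_scores: pd.Series,
) -> pd.DataFrame:
    """Cohort descriptives: means and s.d. of ages, MHT, g and burden totals."""
    rows = []

    def add(name: str, values: pd.Series | np.ndarray) -> None:
        v = pd.Series(values).dropna()
        rows.append(
            {"measure": name, "n": len(v), "mean": v.mean(), "sd": v.std(ddof=1)}
        )

    add("childhood_age_years", cohort["age_child"])
    add("late_life_age_years", cohort["age_late"])
    add("mht_childhood", cohort["mht_child"])
    add("mht_late_life", cohort["mht_late"])
    add("fluid_g", g_scores)
    for thr in sorted(burden_tables):
        add(f"rare_alleles_maf_le_{thr}", burden_tables[thr]["burden_combined_nonsyn"])
    rows.append(
        {
            "measure": "fraction_female",
            "n": len(cohort),
            "mean": cohort["sex_female"].mean(),
            "sd": np.nan,
        }
    )
    return pd.DataFrame(rows)


def run_pipeline(
    matrix: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    maf_thresholds: tuple[float, ...] = assoc_mod.DEFAULT_THRESHOLDS,
    missing_policy: str = "zero",
    outlier_sd: float = 4.0,
    snp_callrate: float = qc_mod.DEFAULT_CALLRATE,
    sample_callrate: float = qc_mod.DEFAULT_CALLRATE,
    m_override: int | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run QC, burden scoring, g derivation and the association grid.

    ``matrix`` must already carry functional classes (apply an annotation
    table first); ``phenotypes`` is the frame from
    :func:`~exoburden.io_genotype.read_phenotypes`. When ``outdir`` is given,
    every report is also written there as TSV.
    """
    logger.info("stage qc: %d samples x %d variants in", matrix.n_samples, matrix.n_variants)
    matrix, qc_report = qc_mod.run_qc(matrix, snp_callrate, sample_callrate)

    matrix, cohort, _ = align_cohort(matrix, phenotypes)

    logger.info("stage burden: computing MAF on %d post-QC variants", matrix.n_variants)
    maf, minor_is_a1 = burden_mod.compute_maf(matrix)
    burden_tables = {
        thr: burden_table(matrix, maf, minor_is_a1, thr, missing_policy)
        for thr in maf_thresholds
    }

    battery_cols = [c for c in cohort.columns if c.startswith("battery_")]
    battery = cohort.set_index("sample_id")[battery_cols]
    g_result = g_mod.derive_fluid_g(battery)
    cohort = cohort.merge(
        g_result.scores.rename("g"), left_on="sample_id", right_index=True, how="left"
    )

    logger.info("stage assoc: fitting sensitivity grid")
    associations = assoc_mod.run_model_grid(
        matrix,
        cohort,
        maf_thresholds=maf_thresholds,
        missing_policy=missing_policy,
        outlier_sd=outlier_sd,
        m_override=m_override,
    )
    association_table = assoc_mod.results_table(associations)
    descriptives = descriptives_table(cohort, burden_tables, g_result.scores)

    outputs: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        qc_report.to_tsv(outdir / "qc_report.tsv")
        outputs["qc_report"] = outdir / "qc_report.tsv"
        for thr, tbl in burden_tables.items():
            p = outdir / f"burden_maf_{thr}.tsv"
            tbl.to_csv(p, sep="\t", index=False, float_format="%.6g")
            outputs[f"burden_{thr}"] = p
        gp = outdir / "gfactor.tsv"
        g_result.scores.rename("g").to_csv(gp, sep="\t", header=True)
        outputs["gfactor"] = gp
        lp = outdir / "gfactor_loadings.tsv"
        g_result.loadings.to_csv(lp, sep="\t", header=True)
        outputs["gfactor_loadings"] = lp
        ap = outdir / "associations.tsv"
        association_table.to_csv(ap, sep="\t", index=False, float_format="%.6g")
        outputs["associations"] = ap
        dp = outdir / "descriptives.tsv"
        descriptives.to_csv(dp, sep="\t", index=False, float_format="%.6g")
        outputs["descriptives"] = dp

    return PipelineResult(
        matrix=matrix,
        qc_report=qc_report,
        burden_tables=burden_tables,
        g_result=g_result,
        associations=associations,
        association_table=association_table,
        descriptives=descriptives,
        outputs=outputs,
    )
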