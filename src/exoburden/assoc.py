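"""Covariate-adjusted linear models of cognition on rare-variant burden.

Each model regresses one cognitive phenotype on the burden score with
mean-centred age (years, centred on the analysis subset) and sex
(female = 1) as covariates. The sensitivity grid crosses MAF thresholds
{0.01, 0.05} with five variant class sets and three phenotypes (childhood
MHT, late-life MHT, late-life g) — 30 models by default — and the burden
term's p-values receive a Bonferroni correction with family size equal to
the number of models actually run, unless overridden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .burden import CLASS_SETS, burden_result, compute_maf, remove_burden_outliers
from .core import GenotypeMatrix
from .errors import AnalysisError

logger = logging.getLogger(__name__)

#: phenotype name -> (cohort column, age column used as covariate)
PHENOTYPES: dict[str, tuple[str, str]] = {
    "mht_child": ("mht_child", "age_child"),
    "mht_late": ("mht_late", "age_late"),
    "g_late": ("g", "age_late"),
}

DEFAULT_THRESHOLDS = (0.01, 0.05)


@dataclass
class AssociationResult:
    """One fitted burden model: unstandardized coefficients, s.e., p-values."""

    phenotype: str
    class_set: str
    maf_threshold: float
    n: int
    coef: pd.DataFrame  # index: term; columns: b, se, p
    p_bonferroni: float | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def burden_b(self) -> float:
        return float(self.coef.loc["burden", "b"])

    @property
    def burden_se(self) -> float:
        return float(self.coef.loc["burden", "se"])

    @property
    def burden_p(self) -> float:
        return float(self.coef.loc["burden", "p"])


def fit_ols(y: np.ndarray, design: np.ndarray, names: list[str]) -> pd.DataFrame:
    """Ordinary least squares with classical (non-robust) standard errors.

    Two-sided p-values come from the t reference distribution with n - k
    degrees of freedom. Raises on rank deficiency, naming the collinear
    columns found via the QR diagonal.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.asarray(design, dtype=np.float64)
    n, k = X.shape
    if n <= k:
        raise AnalysisError(f"need n > k, got n={n}, k={k}")
    if np.linalg.matrix_rank(X) < k:
        _, R = np.linalg.qr(X)
        scale = np.sqrt((X**2).sum(axis=0))
        bad = [names[j] for j in np.flatnonzero(np.abs(np.diag(R)) < 1e-8 * scale)]
        raise AnalysisError(f"design matrix is rank deficient (collinear columns: {bad})")
    fit = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {"b": fit.params, "se": fit.bse, "p": fit.pvalues}, index=names
    )


def diagnostics(residuals: np.ndarray, flag_threshold: float = 4.0) -> dict:
    """Numeric residual diagnostics in place of diagnostic plots.

    Returns residual mean, skew, the largest absolute standardized residual,
    and a flag raised when the latter exceeds ``flag_threshold``.
    """
    residuals = np.asarray(residuals, dtype=np.float64)
    sd = residuals.std(ddof=1)
    std_resid = residuals / sd if sd > 0 else np.zeros_like(residuals)
    max_abs = float(np.abs(std_resid).max())
    return {
        "resid_mean": float(residuals.mean()),
        "resid_skew": float(scipy.stats.skew(residuals)),
        "max_abs_std_resid": max_abs,
        "outlier_flag": bool(max_abs > flag_threshold),
    }


def run_burden_model(
    cohort: pd.DataFrame,
    burden: pd.Series,
    phenotype: str,
    class_set: str = "combined_nonsyn",
    maf_threshold: float = 0.01,
) -> AssociationResult:
    """Fit one phenotype ~ 1 + mean-centred age + sex(female) + burden model.

    The cohort frame must carry ``sample_id``, ``sex_female`` and the
    phenotype/age columns; ``burden`` is indexed by sample id. The analysis
    subset is the complete-case intersection, and the age mean is taken on
    that subset.
    """
    pheno_col, age_col = PHENOTYPES[phenotype]
    df = cohort.set_index("sample_id")[[pheno_col, age_col, "sex_female"]].join(
        burden.rename("burden"), how="inner"
    ).dropna()
    n = len(df)
    if n < 10:
        raise AnalysisError(f"{phenotype}: only {n} complete cases (need >= 10)")
    age_c = df[age_col].to_numpy() - df[age_col].mean()
    X = np.column_stack(
        [np.ones(n), age_c, df["sex_female"].to_numpy(float), df["burden"].to_numpy(float)]
    )
    names = ["intercept", "age", "sex_female", "burden"]
    y = df[pheno_col].to_numpy(float)
    coef = fit_ols(y, X, names)
    resid = y - X @ coef["b"].to_numpy()
    return AssociationResult(
        phenotype=phenotype,
        class_set=class_set,
        maf_threshold=maf_threshold,
        n=n,
        coef=coef,
        diagnostics=diagnostics(resid),
    )


def bonferroni(pvalues: np.ndarray | list[float], m: int) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)``, order preserved."""
    p = np.asarray(pvalues, dtype=np.float64)
    if m <= 0:
        raise ValueError(f"family size m must be positive, got {m}")
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of p-values {p.size}")
    return np.minimum(1.0, m * p)


def run_model_grid(
    matrix: GenotypeMatrix,
    cohort: pd.DataFrame,
    maf_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    class_sets: tuple[str, ...] = tuple(CLASS_SETS),
    phenotypes: tuple[str, ...] = tuple(PHENOTYPES),
    missing_policy: str = "zero",
    outlier_sd: float = 4.0,
    m_override: int | None = None,
) -> list[AssociationResult]:
    """Run the full sensitivity grid on a post-QC matrix and aligned cohort.

    Burden outliers are identified once, on the combined non-synonymous
    burden at the most stringent threshold, and excluded from every model.
    Bonferroni family size is the number of models fitted (or the override).
    """
    maf, minor_is_a1 = compute_maf(matrix)

    primary = burden_result(
        matrix, maf, minor_is_a1, min(maf_thresholds), "combined_nonsyn", missing_policy
    )
    kept, removed = remove_burden_outliers(
        primary.totals, primary.sample_ids, n_sd=outlier_sd
    )
    kept_set = set(kept)

    results: list[AssociationResult] = []
    for thr in maf_thresholds:
        for cs in class_sets:
            br = burden_result(matrix, maf, minor_is_a1, thr, cs, missing_policy)
            if br.n_variants_used == 0:
                logger.warning(
                    "skipping %s at MAF <= %g: empty variant selection", cs, thr
                )
                continue
            series = pd.Series(br.totals, index=br.sample_ids)
            series = series[series.index.isin(kept_set)]
            for ph in phenotypes:
                res = run_burden_model(cohort, series, ph, class_set=cs, maf_threshold=thr)
                results.append(res)

    m = m_override if m_override is not None else len(results)
    adj = bonferroni([r.burden_p for r in results], m)
    for r, pb in zip(results, adj):
        r.p_bonferroni = float(pb)
    if removed:
        logger.info("grid excluded %d burden outlier(s): %s", len(removed), removed)
    return results


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten grid results into the one-row-per-model report table."""
    rows = []
    for r in results:
        row = {
            "phenotype": r.phenotype,
            "maf_threshold": r.maf_threshold,
            "class_set": r.class_set,
            "n": r.n,
        }
        for term in ("age", "sex_female", "burden"):
            for col in ("b", "se", "p"):
                row[f"{col}_{term}"] = r.coef.loc[term, col]
        row["p_bonferroni"] = r.p_bonferroni
        rows.append(row)
    return pd.DataFrame(rows)
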