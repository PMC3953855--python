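"""Fluid general cognitive ability (g) from a late-life test battery.

Cognitive tests correlate positively, so the first principal component of a
battery captures a general dimension. The factor is extracted from the test
correlation matrix (each test z-scored first), its sign is fixed so that
higher g means better performance, and the scores are z-standardized to mean
0, variance 1 (sample variance, n - 1 divisor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnalysisError


@dataclass
class GFactorResult:
    """First-principal-component fluid g scores.

    Attributes
    ----------
    scores : pandas.Series
        Standardized g, indexed by sample id (complete cases only).
    loadings : pandas.Series
        Per-test correlation-scale weights on the first component.
    variance_explained : float
        Fraction of battery variance on the first component.
    n_complete : int
        Number of complete-case samples used.
    """

    scores: pd.Series
    loadings: pd.Series
    variance_explained: float
    n_complete: int


def derive_fluid_g(battery: pd.DataFrame) -> GFactorResult:
    """Derive standardized fluid g from a samples x tests score table.

    Complete-case rows only; requires at least 3 tests and 10 complete cases.
    The component sign is flipped when the loading sum is negative, so a
    positively intercorrelated battery always loads positively.

    Raises
    ------
    AnalysisError
        Fewer than 3 tests or 10 complete cases, or a test with zero variance.
    """
    if battery.shape[1] < 3:
        raise AnalysisError(f"need at least 3 tests, got {battery.shape[1]}")
    complete = battery.dropna(axis=0)
    if len(complete) < 10:
        raise AnalysisError(f"need at least 10 complete cases, got {len(complete)}")

    X = complete.to_numpy(dtype=np.float64)
    sd = X.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        raise AnalysisError(f"test {complete.columns[zero_var[0]]!r} has zero variance")
    Z = (X - X.mean(axis=0)) / sd

    # PCA of the correlation structure via eigendecomposition
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    lam1, w = eigval[order[0]], eigvec[:, order[0]]
    if w.sum() < 0:
        w = -w

    raw = Z @ w
    scores = (raw - raw.mean()) / raw.std(ddof=1)
    return GFactorResult(
        scores=pd.Series(scores, index=complete.index, name="g"),
        loadings=pd.Series(w, index=complete.columns, name="loading"),
        variance_explained=float(lam1 / eigval.sum()),
        n_complete=len(complete),
    )
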