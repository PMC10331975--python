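"""Internal-structure checks: local independence and unidimensionality.

Local independence is screened by pairwise Pearson correlations between item
standardized-residual columns: once the Rasch measure is removed, items
should share no further systematic variance (|r| below 0.7, i.e. shared
variance below 50%).

Unidimensionality is assessed by a principal component analysis of the
standardized residuals.  The percentage of observation variance explained by
the Rasch measures comes from the decomposition of observed variance into
model-expectation variance plus residual variance, and the first-contrast
eigenvalue is the largest eigenvalue of the L×L residual correlation matrix
— on that scale an eigenvalue of 2.0 means "two items' worth" of residual
covariation, the conventional red flag for a secondary dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import AnalysisConfig, InputError, ResponseMatrix
from .rsm import RSMParameters, expected_moments
from .fit import standardized_residuals

__all__ = ["StructureResult", "local_independence", "pca_of_residuals", "residual_correlations"]


@dataclass
class StructureResult:
    residual_correlations: pd.DataFrame
    max_pair: tuple[str, str, float]
    variance_explained_pct: float
    first_contrast_eigenvalue: float
    local_independence_ok: bool
    unidimensional_ok: bool

    def to_dict(self) -> dict:
        return {
            "max_pair": {
                "items": list(self.max_pair[:2]),
                "correlation": self.max_pair[2],
            },
            "variance_explained_pct": self.variance_explained_pct,
            "first_contrast_eigenvalue": self.first_contrast_eigenvalue,
            "local_independence_ok": self.local_independence_ok,
            "unidimensional_ok": self.unidimensional_ok,
        }


def _usable_z(m: ResponseMatrix, p: RSMParameters) -> np.ma.MaskedArray:
    _, z, _ = standardized_residuals(m, p)
    drop = p.extreme_persons[:, None] | p.extreme_items[None, :]
    return np.ma.MaskedArray(np.asarray(z), mask=np.ma.getmaskarray(z) | drop)


def residual_correlations(m: ResponseMatrix, p: RSMParameters) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of standardized residual columns.

    Constant columns yield NaN off-diagonals (undefined correlation).
    """
    if m.n_persons < 3:
        raise InputError("need at least 3 persons for residual correlations")
    z = _usable_z(m, p)
    df = pd.DataFrame(z.filled(np.nan), columns=list(m.items))
    corr = df.corr(min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def local_independence(
    m: ResponseMatrix, p: RSMParameters, cfg: AnalysisConfig | None = None
):
    """Residual-correlation screen for local independence.

    Returns (correlation matrix, (item_a, item_b, r_max), verdict); the
    verdict passes iff max |r| over distinct pairs is below
    ``residual_corr_max``.
    """
    cfg = cfg or AnalysisConfig()
    corr = residual_correlations(m, p)
    a = corr.values.copy()
    np.fill_diagonal(a, np.nan)
    if np.all(np.isnan(a)):
        raise InputError("all residual correlations undefined")
    flat = np.nanargmax(np.abs(a))
    i, j = np.unravel_index(flat, a.shape)
    pair = (corr.index[i], corr.columns[j], float(a[i, j]))
    ok = bool(abs(pair[2]) < cfg.residual_corr_max)
    return corr, pair, ok


def pca_of_residuals(
    m: ResponseMatrix, p: RSMParameters, cfg: AnalysisConfig | None = None
) -> StructureResult:
    """Variance explained by the Rasch measures and first-contrast eigenvalue.

    variance_explained_pct = 100 * sum_i Var_n(E_ni) /
                                   (sum_i Var_n(E_ni) + sum_i Var_n(e_ni))
    over non-extreme persons and items; the first contrast is the largest
    eigenvalue of the residual correlation matrix (eigenvalues sum to L).
    """
    cfg = cfg or AnalysisConfig()
    corr, pair, li_ok = local_independence(m, p, cfg)

    core_p = ~p.extreme_persons
    core_i = ~p.extreme_items
    e, _, _ = expected_moments(p.theta[:, None], p.delta[None, :], p.tau)
    coded = m.coded()
    resid = coded.astype(float) - e
    e_m = np.ma.MaskedArray(e, mask=coded.mask)
    sub = np.ix_(core_p, core_i)
    var_model = float(e_m[sub].var(axis=0, ddof=1).sum())
    var_resid = float(resid[sub].var(axis=0, ddof=1).sum())
    total = var_model + var_resid
    vexp = 100.0 * var_model / total if total > 0 else float("nan")

    a = corr.values.copy()
    defined = ~np.isnan(a).all(axis=0)
    a = a[np.ix_(defined, defined)]
    a = np.where(np.isnan(a), 0.0, a)  # pairwise-NaN entries treated as 0 covariation
    eigvals = np.linalg.eigvalsh(a)
    first_contrast = float(eigvals.max()) if a.size else float("nan")

    uni_ok = bool(
        vexp >= cfg.variance_explained_min
        and first_contrast < cfg.first_contrast_eigen_max
    )
    return StructureResult(corr, pair, vexp, first_contrast, li_ok, uni_ok)
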