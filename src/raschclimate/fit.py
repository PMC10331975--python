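"""Residual-based item and person fit statistics.

Outfit MnSq is the unweighted mean of squared standardized residuals; infit
MnSq is the information-weighted version (sum of squared raw residuals over
summed model variances).  Both have expectation 1 under model fit.
Standardized values use the Wilson-Hilferty cube-root transform with the
model-based variance built from the cell variance W and fourth central
moment C, the convention of the Winsteps family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import AnalysisConfig, InputError, ResponseMatrix
from .rsm import RSMParameters, expected_moments

__all__ = [
    "FitTable",
    "standardized_residuals",
    "item_fit",
    "person_fit",
    "classify_item_fit",
    "flag_persons",
    "flag_rate",
]


@dataclass
class FitTable:
    """Per-entity fit statistics (items or persons).

    Entities with no usable observations carry NaN mean squares and
    ``defined`` False.
    """

    table: pd.DataFrame  # id-indexed: infit_mnsq, infit_z, outfit_mnsq, outfit_z, n_obs, defined

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _cell_moments(m: ResponseMatrix, p: RSMParameters):
    if len(p.theta) != m.n_persons or len(p.delta) != m.n_items:
        raise InputError("parameter dimensions do not match the response matrix")
    e, w, c = expected_moments(p.theta[:, None], p.delta[None, :], p.tau)
    return e, w, c


def standardized_residuals(m: ResponseMatrix, p: RSMParameters):
    """Raw residuals e = x - E and standardized residuals z = e/sqrt(W).

    Returns masked arrays (e, z, w): missing cells propagate as masked.
    """
    e_exp, w, _ = _cell_moments(m, p)
    coded = m.coded()
    resid = coded.astype(float) - e_exp
    z = resid / np.sqrt(np.maximum(w, 1e-300))
    wm = np.ma.MaskedArray(w, mask=coded.mask)
    return resid, z, wm


def _mnsq_and_z(resid, z, w, c, axis, usable):
    """Mean squares and Wilson-Hilferty standardized z along one axis."""
    n = usable.sum(axis=axis).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        outfit = np.where(n > 0, (z**2 * usable).sum(axis=axis) / n, np.nan)
        sw = (w * usable).sum(axis=axis)
        infit = np.where(sw > 0, (resid**2 * usable).sum(axis=axis) / sw, np.nan)
        # variance of outfit: sum(C/W^2)/n^2 - 1/n ; of infit: sum(C - W^2)/(sum W)^2
        with np.errstate(invalid="ignore", divide="ignore"):
            cw2 = np.where(usable, c / np.maximum(w, 1e-300) ** 2, 0.0)
        q2_out = np.where(n > 0, cw2.sum(axis=axis) / n**2 - 1.0 / n, np.nan)
        q2_in = np.where(sw > 0, ((c - w**2) * usable).sum(axis=axis) / sw**2, np.nan)
        q_out = np.sqrt(np.maximum(q2_out, 1e-12))
        q_in = np.sqrt(np.maximum(q2_in, 1e-12))
        z_out = (np.cbrt(outfit) - 1.0) * (3.0 / q_out) + q_out / 3.0
        z_in = (np.cbrt(infit) - 1.0) * (3.0 / q_in) + q_in / 3.0
    return outfit, infit, z_out, z_in, n


def _fit_frame(ids, outfit, infit, z_out, z_in, n, measures, ses) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "measure": measures,
            "se": ses,
            "infit_mnsq": infit,
            "infit_z": z_in,
            "outfit_mnsq": outfit,
            "outfit_z": z_out,
            "n_obs": n.astype(int),
            "defined": np.isfinite(infit),
        },
        index=list(ids),
    )
    df.index.name = "id"
    return df


def item_fit(m: ResponseMatrix, p: RSMParameters) -> FitTable:
    """Infit/outfit mean squares and standardized values per item.

    Observations from extreme persons carry no residual information (their
    measures are assigned, not estimated) and are excluded; an item whose
    observations all come from extreme persons is marked undefined.
    """
    e_exp, w, c = _cell_moments(m, p)
    coded = m.coded()
    usable = (~coded.mask) & (~p.extreme_persons[:, None])
    resid = coded.filled(0).astype(float) - e_exp
    z = resid / np.sqrt(np.maximum(w, 1e-300))
    outfit, infit, z_out, z_in, n = _mnsq_and_z(resid, z, w, c, 0, usable)
    return FitTable(_fit_frame(m.items, outfit, infit, z_out, z_in, n, p.delta, p.se_delta))


def person_fit(m: ResponseMatrix, p: RSMParameters) -> FitTable:
    """Infit/outfit mean squares and standardized values per person.

    Extreme persons (all-minimum / all-maximum patterns) have no residual
    variation and are marked undefined.
    """
    e_exp, w, c = _cell_moments(m, p)
    coded = m.coded()
    usable = (~coded.mask) & (~p.extreme_items[None, :]) & (~p.extreme_persons[:, None])
    resid = coded.filled(0).astype(float) - e_exp
    z = resid / np.sqrt(np.maximum(w, 1e-300))
    outfit, infit, z_out, z_in, n = _mnsq_and_z(resid, z, w, c, 1, usable)
    return FitTable(_fit_frame(m.persons, outfit, infit, z_out, z_in, n, p.theta, p.se_theta))


def classify_item_fit(fit: FitTable, cfg: AnalysisConfig) -> pd.Series:
    """Per-item verdict: 'fit' inside the closed infit interval, else 'misfit'.

    The acceptance interval is treated as closed ([0.7, 1.3] by default), so
    a boundary value passes.
    """
    infit = fit["infit_mnsq"]
    misfit = (infit < cfg.item_infit_lo) | (infit > cfg.item_infit_hi)
    out = pd.Series(np.where(misfit, "misfit", "fit"), index=infit.index)
    out[infit.isna()] = "undefined"
    return out


def flag_persons(fit: FitTable, cfg: AnalysisConfig) -> pd.Series:
    """Person misfit flag: infit MnSq >= 1.4 AND infit z >= 2 (conjunction)."""
    return (fit["infit_mnsq"] >= cfg.person_infit_max) & (
        fit["infit_z"] >= cfg.person_z_max
    )


def flag_rate(fit: FitTable, cfg: AnalysisConfig) -> float:
    """Proportion of persons flagged among all persons in the table."""
    flags = flag_persons(fit, cfg)
    return float(flags.sum()) / len(flags)
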