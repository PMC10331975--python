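"""Rating-scale (category) functioning diagnostics.

Checks that the five response categories behave as an ordered scale: the
average person measure within each category should advance monotonically,
and each step calibration's outfit mean square should stay below 2.0.  Also
produces the category-probability-curve traces whose adjacent-category
crossings are the Andrich thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import AnalysisConfig, ResponseMatrix
from .rsm import RSMParameters, category_probabilities, expected_moments

__all__ = ["CategoryDiagnostics", "category_diagnostics", "category_curves", "collapse_categories"]


@dataclass
class CategoryDiagnostics:
    """Per-category usage, average measures and outfit; per-step thresholds."""

    table: pd.DataFrame        # per category: count, avg_measure, outfit_mnsq
    thresholds: np.ndarray     # Andrich step calibrations tau_1..tau_K
    monotonic: bool
    outfit_ok: bool
    per_item_monotonic: pd.Series | None = None

    @property
    def passes(self) -> bool:
        return self.monotonic and self.outfit_ok


def category_diagnostics(
    m: ResponseMatrix,
    p: RSMParameters,
    cfg: AnalysisConfig | None = None,
    per_item: bool = False,
) -> CategoryDiagnostics:
    """Category-functioning diagnostics pooled across items.

    Average measure per category is the mean theta of persons contributing
    observations in that category (pooled, since the rating-scale model
    shares one category structure); category outfit is the mean squared
    standardized residual over those observations.  The verdict passes iff
    the average measures are non-decreasing and every category outfit is
    below ``category_outfit_max``.  An empty category yields NaN entries and
    the monotonicity check skips it.
    """
    cfg = cfg or AnalysisConfig()
    coded = m.coded()
    kmax = m.max_category
    use = (~coded.mask) & (~p.extreme_persons[:, None]) & (~p.extreme_items[None, :])
    e, w, _ = expected_moments(p.theta[:, None], p.delta[None, :], p.tau)
    z2 = (coded.filled(0).astype(float) - e) ** 2 / np.maximum(w, 1e-300)
    theta_cells = np.broadcast_to(p.theta[:, None], coded.shape)

    counts = np.zeros(kmax + 1, dtype=int)
    avg = np.full(kmax + 1, np.nan)
    outfit = np.full(kmax + 1, np.nan)
    x = coded.filled(-1)
    for k in range(kmax + 1):
        sel = use & (x == k)
        counts[k] = int(sel.sum())
        if counts[k]:
            avg[k] = theta_cells[sel].mean()
            outfit[k] = z2[sel].mean()

    observed = ~np.isnan(avg)
    monotonic = bool(np.all(np.diff(avg[observed]) >= 0))
    outfit_ok = bool(np.all(outfit[observed] < cfg.category_outfit_max))

    table = pd.DataFrame(
        {"count": counts, "avg_measure": avg, "outfit_mnsq": outfit},
        index=pd.Index(range(1, kmax + 2), name="category"),
    )

    per_item_flags = None
    if per_item:
        flags = {}
        for i, item in enumerate(m.items):
            av = np.full(kmax + 1, np.nan)
            for k in range(kmax + 1):
                sel = use[:, i] & (x[:, i] == k)
                if sel.any():
                    av[k] = p.theta[sel].mean()
            obs = ~np.isnan(av)
            flags[item] = bool(np.all(np.diff(av[obs]) >= 0))
        per_item_flags = pd.Series(flags)

    return CategoryDiagnostics(table, p.tau.copy(), monotonic, outfit_ok, per_item_flags)


def category_curves(
    p: RSMParameters, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Category probability traces over a grid of theta - delta.

    Adjacent-category curves k-1 and k cross exactly at tau_k (the Andrich
    threshold): there the two numerator terms are equal.
    """
    if grid is None:
        span = max(4.0, float(np.abs(p.tau).max()) + 2.0)
        grid = np.linspace(-span, span, 201)
    grid = np.asarray(grid, dtype=float)
    probs = category_probabilities(grid, 0.0, p.tau)
    cols = {f"p{k + 1}": probs[:, k] for k in range(probs.shape[1])}
    return pd.DataFrame({"relative_measure": grid, **cols})


def collapse_categories(m: ResponseMatrix, merge_map: dict[int, int]) -> ResponseMatrix:
    """Merge rating-scale categories via an external-code map.

    ``merge_map`` sends original 1-based codes to new 1-based codes; codes not
    in the map are kept.  The result is re-coded to consecutive categories
    1..K'.  Provided as a transformation only — the protocol keeps the
    original five categories by default.
    """
    mapped = np.vectorize(lambda v: merge_map.get(v, v))(m.values)
    levels = np.unique(mapped[~m.missing_mask])
    recode = {old: new + 1 for new, old in enumerate(sorted(levels))}
    values = np.vectorize(lambda v: recode.get(v, 1))(mapped)
    return ResponseMatrix(values, m.persons, m.items, len(levels), m.missing_mask)
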