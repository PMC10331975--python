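"""Mantel chi-square differential item functioning for polytomous items.

For a two-group comparison the respondents are stratified by a matching
variable (here: total raw score on the retained items, the sufficient
statistic for the Rasch measure under complete data).  Within stratum s the
focal group's observed item-score sum O_s is compared with its expectation
E_s and variance V_s under random allocation of group labels (multivariate
hypergeometric model):

    E_s = n_f,s * mean(scores in s)
    V_s = n_f,s * n_r,s / (n_s * (n_s - 1)) * sum_s (score - mean)^2
    chi2 = (sum_s O_s - sum_s E_s)^2 / sum_s V_s,   df = 1

Multi-level factors are compared pairwise; Bonferroni adjustment uses the
per-factor family (items × group pairs).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .io_model import AnalysisConfig, FactorTable, InputError, ResponseMatrix
from .rsm import RSMParameters

__all__ = ["DIFResult", "mantel_polytomous", "dif_scan", "score_strata"]


@dataclass
class DIFResult:
    """All item × factor × group-pair Mantel tests with verdict flags."""

    table: pd.DataFrame  # item, factor, group_a, group_b, chi2, p_raw, p_adj, direction, n_strata, flagged
    alpha: float

    @property
    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]

    def any_dif(self) -> bool:
        return bool(self.table["flagged"].any())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def mantel_polytomous(scores, groups, strata):
    """Mantel test for a polytomous item between two groups across strata.

    Parameters
    ----------
    scores : integer item scores (any consistent coding; categories enter as
        integer scores)
    groups : labels with exactly two distinct values; the lexicographically
        second value is the focal group
    strata : stratum labels of the matching variable

    Returns (chi2, p, direction, n_strata_used); ``direction`` > 0 means the
    focal group scores higher than expected (finds the item easier to
    endorse).  Strata containing only one group are dropped; if all strata
    drop, the result is undefined (NaN).
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    strata = np.asarray(strata)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise InputError(f"mantel_polytomous needs exactly 2 groups, got {levels}")
    focal = levels[1]

    num = 0.0
    var = 0.0
    used = 0
    for s in np.unique(strata):
        sel = strata == s
        g = groups[sel]
        y = scores[sel]
        nf = int((g == focal).sum())
        nr = int((g != focal).sum())
        n = nf + nr
        if nf == 0 or nr == 0 or n < 2:
            continue
        o = y[g == focal].sum()
        e = nf * y.mean()
        v = nf * nr / (n * (n - 1)) * ((y - y.mean()) ** 2).sum()
        num += o - e
        var += v
        used += 1
    if used == 0 or var <= 0:
        return float("nan"), float("nan"), 0.0, used
    stat = num**2 / var
    p = float(chi2_dist.sf(stat, df=1))
    return float(stat), p, float(np.sign(num)), used


def score_strata(
    m: ResponseMatrix, items: list[str] | None = None, min_size: int = 10
) -> np.ndarray:
    """Stratify persons by total raw score on an item subset.

    Adjacent raw-score levels are merged until every stratum holds at least
    ``min_size`` respondents (a trailing small stratum merges backwards).
    """
    sub = m if items is None else m.subset_items(items)
    totals = sub.coded().filled(0).sum(axis=1)
    order = np.sort(np.unique(totals))
    bands = []
    current = []
    count = 0
    for s in order:
        current.append(s)
        count += int((totals == s).sum())
        if count >= min_size:
            bands.append(list(current))
            current, count = [], 0
    if current:
        if bands:
            bands[-1].extend(current)
        else:
            bands.append(list(current))
    label = np.empty(len(totals), dtype=int)
    for b, scores in enumerate(bands):
        label[np.isin(totals, scores)] = b
    return label


def dif_scan(
    m: ResponseMatrix,
    p: RSMParameters,
    factors: FactorTable,
    cfg: AnalysisConfig | None = None,
    items: list[str] | None = None,
) -> DIFResult:
    """Mantel DIF scan over every item × factor × group-pair.

    Persons lacking a factor value are excluded from that factor's tests
    only.  Factor levels with fewer than ``dif_min_group_size`` respondents
    are excluded with a warning entry.  Bonferroni: within each factor the
    family is items × group-pairs; adjusted p = min(1, p * family size).
    """
    cfg = cfg or AnalysisConfig()
    item_set = list(items) if items is not None else list(m.items)
    sub = m.subset_items(item_set)
    strata = score_strata(sub, min_size=cfg.dif_min_stratum_size)
    coded = sub.coded().filled(0)
    aligned = factors.aligned_to(m)

    rows = []
    for factor in factors.factor_names():
        col = aligned[factor]
        level_counts = col.value_counts()
        levels = sorted(
            l for l, c in level_counts.items() if c >= cfg.dif_min_group_size
        )
        pairs = list(combinations(levels, 2))
        family = len(item_set) * len(pairs)
        for ga, gb in pairs:
            keep = col.isin([ga, gb]).to_numpy()
            for j, item in enumerate(item_set):
                stat, praw, direction, used = mantel_polytomous(
                    coded[keep, j], col.to_numpy()[keep], strata[keep]
                )
                padj = min(1.0, praw * family) if np.isfinite(praw) else float("nan")
                rows.append(
                    {
                        "item": item,
                        "factor": factor,
                        "group_a": ga,
                        "group_b": gb,
                        "chi2": stat,
                        "p_raw": praw,
                        "p_adj": padj,
                        "direction": direction,
                        "n_strata": used,
                        "flagged": bool(np.isfinite(padj) and padj < cfg.dif_alpha),
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "item", "factor", "group_a", "group_b", "chi2",
            "p_raw", "p_adj", "direction", "n_strata", "flagged",
        ],
    )
    return DIFResult(table, cfg.dif_alpha)
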