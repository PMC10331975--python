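"""Precision and reliability: person separation, strata, floor/ceiling, targeting.

Person-separation reliability R is the Rasch analogue of KR-20/Cronbach
alpha: the share of observed person-measure variance not attributable to
measurement error.  The separation index G = sqrt(R/(1-R)) expresses the
"true" spread in error units; G >= 2 supports distinguishing at least three
statistically distinct levels, counted by the strata formula H = (4G+1)/3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import AnalysisConfig, InputError, ResponseMatrix
from .rsm import RSMParameters

__all__ = ["ReliabilityResult", "reliability", "wright_map", "cronbach_alpha"]


@dataclass
class ReliabilityResult:
    observed_variance: float
    mean_se_squared: float
    person_reliability: float     # R in [0, 1)
    separation_index: float       # G = sqrt(R/(1-R))
    strata: float                 # H = (4G+1)/3
    cronbach_alpha: float         # raw-score internal consistency, for reference
    floor_count: int
    ceiling_count: int
    floor_pct: float
    ceiling_pct: float
    targeting_offset: float       # mean person measure - mean item difficulty
    passes: bool
    note: str = ""

    def to_dict(self) -> dict:
        return {
            k: (v if not isinstance(v, (np.floating, np.integer)) else v.item())
            for k, v in self.__dict__.items()
        }


def cronbach_alpha(m: ResponseMatrix) -> float:
    """Raw-score Cronbach alpha over complete response rows."""
    coded = m.coded()
    rows = ~coded.mask.any(axis=1)
    x = coded.filled(0)[rows].astype(float)
    if x.shape[0] < 2:
        raise InputError("need at least 2 complete rows for alpha")
    l = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(l / (l - 1) * (1 - item_var / total_var))


def reliability(
    m: ResponseMatrix, p: RSMParameters, cfg: AnalysisConfig | None = None
) -> ReliabilityResult:
    """Person-separation reliability, separation and strata with floor/ceiling.

    R and G are computed over non-extreme persons (extreme measures are
    extrapolated, their SEs are not comparable); floor/ceiling counts scan
    the raw response patterns of everyone.  The verdict passes iff
    G >= separation_min and R >= reliability_min.
    """
    cfg = cfg or AnalysisConfig()
    core = ~p.extreme_persons
    if core.sum() < 2:
        raise InputError("need at least 2 non-extreme persons")
    theta = p.theta[core]
    se2 = p.se_theta[core] ** 2
    obs_var = float(theta.var(ddof=1))
    mse = float(se2.mean())

    note = ""
    if obs_var <= 0:
        r = float("nan")
        g = float("nan")
        h = float("nan")
        passes = False
        note = "observed person-measure variance is zero; reliability undefined"
    else:
        r = max(0.0, (obs_var - mse) / obs_var)
        g = float(np.sqrt(r / (1 - r))) if r < 1 else float("inf")
        h = (4 * g + 1) / 3
        passes = bool(g >= cfg.separation_min and r >= cfg.reliability_min)

    coded = m.coded()
    complete = ~coded.mask.any(axis=1)
    x = coded.filled(-1)
    kmax = m.max_category
    floor = complete & (x == 0).all(axis=1)
    ceiling = complete & (x == kmax).all(axis=1)
    n = m.n_persons

    return ReliabilityResult(
        observed_variance=obs_var,
        mean_se_squared=mse,
        person_reliability=float(r),
        separation_index=float(g),
        strata=float(h),
        cronbach_alpha=cronbach_alpha(m),
        floor_count=int(floor.sum()),
        ceiling_count=int(ceiling.sum()),
        floor_pct=100.0 * floor.sum() / n,
        ceiling_pct=100.0 * ceiling.sum() / n,
        targeting_offset=float(p.theta.mean() - p.delta.mean()),
        passes=passes,
        note=note,
    )


def wright_map(p: RSMParameters, bin_width: float = 0.5):
    """Joint person/item distribution on the common logit axis.

    Returns (bin table, monospaced text rendering).  Each item identifier
    appears exactly once in the rendering.
    """
    lo = np.floor(min(p.theta.min(), p.delta.min()) / bin_width) * bin_width
    hi = np.ceil(max(p.theta.max(), p.delta.max()) / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    person_counts, _ = np.histogram(p.theta, bins=edges)
    item_bins = np.clip(np.digitize(p.delta, edges) - 1, 0, len(edges) - 2)

    rows = []
    lines = ["      measure | persons        | items", "      --------+----------------+------"]
    for b in range(len(edges) - 2, -1, -1):
        centre = (edges[b] + edges[b + 1]) / 2
        names = [p.items[i] if p.items else str(i) for i in np.where(item_bins == b)[0]]
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "person_count": int(person_counts[b]),
                "items": " ".join(names),
            }
        )
        bar = "#" * min(int(person_counts[b]), 60)
        lines.append(f"{centre:12.2f}  | {bar:<15}| {' '.join(names)}")
    offset = float(p.theta.mean() - p.delta.mean())
    lines.append(f"targeting offset (persons - items): {offset:+.2f} logits")
    return pd.DataFrame(rows), "\n".join(lines)
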