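"""Synthetic response-matrix generation.

The study's raw 761×11 response matrix is not public, so every pipeline
stage is exercised on simulated data drawn from the same generative family
the analysis assumes: a unidimensional rating-scale Rasch process over a
normally distributed cohort, optionally contaminated with the pathologies
the protocol is designed to detect — uniform DIF for a focal group, an
additive secondary trait on an item subset, and careless (uniform-random)
responders.  A separate helper rebuilds a matrix whose per-item category
frequencies match the published marginal counts exactly; its joint structure
is random, so it validates I/O and marginal bookkeeping, not fitted
statistics.

The default cohort emulates the published survey's shape: N=761 persons,
11 five-category items, item difficulties spread over about one logit, and
a cohort mean high enough above the items that roughly 5% of respondents
hit the ceiling (all-maximum pattern), matching the strongly right-skewed
published marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import FactorTable, InputError, ResponseMatrix, classify_enps
from .rsm import category_probabilities

__all__ = [
    "SimulationConfig",
    "DIFSpec",
    "SecondDimensionSpec",
    "simulate_responses",
    "fixture_from_marginals",
    "hse_default_config",
    "HSE_TABLE2_COUNTS",
    "HSE_ITEMS",
]

HSE_ITEMS = tuple(f"HSE{i}" for i in range(1, 12))

# Published per-item category counts (items 1..11 × categories 1..5), N = 761.
HSE_TABLE2_COUNTS = np.array(
    [
        [5, 33, 116, 294, 313],
        [11, 17, 97, 372, 264],
        [4, 22, 99, 359, 277],
        [13, 40, 140, 339, 229],
        [1, 4, 15, 256, 485],
        [2, 1, 28, 282, 448],
        [5, 11, 67, 278, 400],
        [10, 32, 197, 376, 146],
        [12, 32, 148, 342, 227],
        [15, 25, 92, 269, 360],
        [34, 62, 284, 252, 129],
    ],
    dtype=int,
)


@dataclass(frozen=True)
class DIFSpec:
    """Uniform DIF: ``shift`` logits added to ``item``'s difficulty for
    persons whose ``factor`` equals ``focal_level`` (positive shift makes the
    item harder to endorse for the focal group)."""

    item: str
    factor: str
    focal_level: str
    shift: float


@dataclass(frozen=True)
class SecondDimensionSpec:
    """Additive secondary trait: u_n ~ N(0, trait_sd) enters the person
    location as theta + loading*u on the listed items only."""

    items: tuple[str, ...]
    loading: float = 0.8
    trait_sd: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of the generative process."""

    n_persons: int = 761
    items: tuple[str, ...] = HSE_ITEMS
    n_categories: int = 5
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    delta: tuple[float, ...] | None = None   # None -> uniform grid over delta_range
    delta_range: tuple[float, float] = (-0.5, 0.5)
    tau: tuple[float, ...] | None = None     # None -> evenly spread, sum 0
    dif_specs: tuple[DIFSpec, ...] = ()
    second_dimension: SecondDimensionSpec | None = None
    careless_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_persons < 2 or len(self.items) < 2:
            raise InputError("need at least 2 persons and 2 items")
        if self.theta_sd < 0:
            raise InputError("theta_sd must be non-negative")
        if not 0 <= self.careless_fraction < 1:
            raise InputError("careless_fraction must lie in [0, 1)")
        for spec in self.dif_specs:
            if not np.isfinite(spec.shift):
                raise InputError("DIF shift must be finite")
            if spec.item not in self.items:
                raise InputError(f"DIF item {spec.item!r} not in item list")
        if self.delta is not None and len(self.delta) != len(self.items):
            raise InputError("delta length must match item count")
        if self.tau is not None:
            tau = np.asarray(self.tau, float)
            if len(tau) != self.n_categories - 1:
                raise InputError("tau length must be n_categories - 1")
            if abs(tau.sum()) > 1e-8:
                raise InputError("tau must sum to 0")

    def resolved_delta(self) -> np.ndarray:
        if self.delta is not None:
            return np.asarray(self.delta, float)
        lo, hi = self.delta_range
        d = np.linspace(lo, hi, len(self.items))
        return d - d.mean()

    def resolved_tau(self) -> np.ndarray:
        if self.tau is not None:
            return np.asarray(self.tau, float)
        k = self.n_categories - 1
        t = np.linspace(-1.5, 1.5, k)
        return t - t.mean()


# Table-1-like background composition of the study organisation (proportions
# of respondents; eNPS raw scores only partially available there, mirrored by
# a missing fraction here).
_FACTOR_LEVELS = {
    "gender": (("female", "male"), (673 / 761, 88 / 761)),
    "employee_type": (("manager", "co-worker"), (137 / 761, 624 / 761)),
    "age_group": (("<45", "45-55", ">55"), (233 / 761, 225 / 761, 303 / 761)),
    "tenure_band": (("<3", "3-10", ">10"), (210 / 761, 399 / 761, 152 / 761)),
}
_ENPS_AVAILABLE = (109 + 118 + 76) / 761


def _draw_factors(rng: np.random.Generator, persons: tuple[str, ...]) -> FactorTable:
    n = len(persons)
    data = {"person": list(persons)}
    for name, (levels, probs) in _FACTOR_LEVELS.items():
        data[name] = rng.choice(levels, size=n, p=np.asarray(probs) / sum(probs))
    # eNPS raw scores: available for a subset, spread to roughly match the
    # detractor/passive/promoter split of the study sample
    raw = np.full(n, np.nan)
    has = rng.random(n) < _ENPS_AVAILABLE
    cls_probs = np.array([109, 118, 76], dtype=float)
    cls_probs /= cls_probs.sum()
    cls = rng.choice(3, size=int(has.sum()), p=cls_probs)
    pick = np.empty(len(cls), dtype=int)
    pick[cls == 0] = rng.integers(0, 7, size=(cls == 0).sum())
    pick[cls == 1] = rng.integers(7, 9, size=(cls == 1).sum())
    pick[cls == 2] = rng.integers(9, 11, size=(cls == 2).sum())
    raw[has] = pick
    df = pd.DataFrame(data)
    df["enps_raw"] = pd.array(
        [int(v) if np.isfinite(v) else pd.NA for v in raw], dtype="Int64"
    )
    return FactorTable(df)


def simulate_responses(cfg: SimulationConfig):
    """Draw a response matrix (plus factors and ground truth) from the model.

    Order of construction: person abilities, factor labels, DIF shifts for
    focal-group members, secondary-trait contributions, category sampling
    from the rating-scale model, then careless-person overwrite.  Fully
    reproducible from ``cfg.seed``.

    Returns
    -------
    (ResponseMatrix, FactorTable, truth) where ``truth`` holds the generating
    theta, delta, tau, and the indices of contaminated persons/items.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_persons
    items = tuple(cfg.items)
    l = len(items)
    kmax = cfg.n_categories - 1
    persons = tuple(f"P{i + 1:04d}" for i in range(n))

    theta = rng.normal(cfg.theta_mean, cfg.theta_sd, size=n)
    delta = cfg.resolved_delta()
    tau = cfg.resolved_tau()
    factors = _draw_factors(rng, persons)
    aligned = factors.table.reindex(list(persons))

    # per-person effective item difficulty, possibly shifted by DIF
    delta_eff = np.broadcast_to(delta, (n, l)).copy()
    for spec in cfg.dif_specs:
        focal = (aligned[spec.factor] == spec.focal_level).to_numpy()
        delta_eff[focal, items.index(spec.item)] += spec.shift

    # per-cell person location, possibly raised by a secondary trait
    theta_eff = np.broadcast_to(theta[:, None], (n, l)).copy()
    if cfg.second_dimension is not None:
        sd = cfg.second_dimension
        u = rng.normal(0.0, sd.trait_sd, size=n)
        for item in sd.items:
            theta_eff[:, items.index(item)] += sd.loading * u

    probs = category_probabilities(theta_eff, delta_eff, tau)
    cum = probs.cumsum(axis=-1)
    draws = rng.random((n, l))
    coded = (draws[..., None] > cum).sum(axis=-1)

    careless = np.zeros(n, dtype=bool)
    n_careless = int(round(cfg.careless_fraction * n))
    if n_careless:
        idx = rng.choice(n, size=n_careless, replace=False)
        careless[idx] = True
        coded[careless] = rng.integers(0, kmax + 1, size=(n_careless, l))

    matrix = ResponseMatrix(coded + 1, persons, items, cfg.n_categories)
    truth = {
        "theta": theta,
        "delta": delta,
        "tau": tau,
        "careless_persons": np.where(careless)[0],
        "config": cfg,
    }
    return matrix, factors, truth


def fixture_from_marginals(
    counts: np.ndarray,
    seed: int = 0,
    items: tuple[str, ...] | None = None,
    n_categories: int | None = None,
) -> ResponseMatrix:
    """Build a matrix whose per-item category frequencies match ``counts``
    exactly (rows: items, columns: categories 1..C; all rows must share one
    total N).

    Each item's column is an independently shuffled multiset, so the joint
    person×item structure is random: the fixture validates marginal
    bookkeeping and I/O, not fitted statistics.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 2:
        raise InputError("counts must be an items × categories table")
    totals = counts.sum(axis=1)
    if len(set(totals.tolist())) != 1:
        raise InputError(f"count rows must share one total, got {sorted(set(totals))}")
    n = int(totals[0])
    l, c = counts.shape
    n_categories = n_categories or c
    rng = np.random.default_rng(seed)
    values = np.empty((n, l), dtype=int)
    for i in range(l):
        col = np.repeat(np.arange(1, c + 1), counts[i])
        rng.shuffle(col)
        values[:, i] = col
    items = items or tuple(f"I{i + 1}" for i in range(l))
    persons = tuple(f"P{i + 1:04d}" for i in range(n))
    return ResponseMatrix(values, persons, items, n_categories)


def hse_default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default cohort emulating the published survey's shape.

    N=761, 11 items, 5 categories.  Item difficulties spread over ~1 logit
    with the patient-involvement item hardest (the published marginals show
    far less agreement there).  Thresholds place category 2 in a narrow band
    (the published category-probability curves show it almost covered by its
    neighbours), and the cohort mean sits ~2 logits above the average item so
    that about 5% of respondents return an all-maximum pattern.
    """
    delta = (-0.15, 0.0, -0.05, 0.25, -0.85, -0.75, -0.45, 0.45, 0.2, -0.1, 1.45)
    tau = (-1.8, -1.5, 0.3, 3.0)
    cfg = SimulationConfig(
        n_persons=761,
        items=HSE_ITEMS,
        n_categories=5,
        theta_mean=2.5,
        theta_sd=2.0,
        delta=delta,
        tau=tau,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
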