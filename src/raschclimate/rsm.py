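"""Andrich rating-scale model: category probabilities and JMLE estimation.

The model places person ability ``theta`` and item difficulty ``delta`` on a
common logit scale with one shared vector of category thresholds ``tau``
(step calibrations).  For internal categories 0..K,

    P(X = k | theta, delta, tau) ∝ exp( sum_{j<=k} (theta - delta - tau_j) )

with an empty sum for k = 0.  Estimation is joint maximum likelihood (JMLE):
alternating Newton-Raphson sweeps over persons, items, and thresholds, with
the identification constraints mean(delta) = 0 over non-extreme items and
sum(tau) = 0 re-applied each cycle.  Persons and items with minimum or
maximum raw scores carry no likelihood information about their own location;
they are excluded from estimation and assigned measures afterwards at a
fractionally adjusted raw score.

JMLE is used because it is the estimator of the Winsteps family of programs
that this protocol mirrors; its known finite-test bias (order (L-1)/L for
dichotomous data) is accepted and an optional correction flag is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .io_model import InputError, ResponseMatrix

__all__ = [
    "RSMParameters",
    "EstimationSettings",
    "ConvergenceError",
    "category_probabilities",
    "expected_moments",
    "fit_jmle",
    "score_to_measure",
]


class ConvergenceError(RuntimeError):
    """JMLE failed to converge; carries the per-cycle change trajectory."""

    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class EstimationSettings:
    """Numerical controls for JMLE."""

    max_iterations: int = 200
    convergence_tol: float = 1e-4   # max absolute logit change per cycle
    extreme_adjust: float = 0.3     # fractional-score correction for extremes
    step_cap: float = 1.0           # max Newton step, logits
    bias_correction: bool = False   # optional (L-1)/L shrinkage of theta, delta

    def __post_init__(self):
        if not self.convergence_tol > 0:
            raise InputError("convergence_tol must be positive")
        if not 0 < self.extreme_adjust < 0.5:
            raise InputError("extreme_adjust must lie in (0, 0.5)")


@dataclass
class RSMParameters:
    """Fitted rating-scale model parameters with standard errors."""

    theta: np.ndarray          # per person, logits
    delta: np.ndarray          # per item, logits
    tau: np.ndarray            # K shared thresholds, logits, sum 0
    se_theta: np.ndarray
    se_delta: np.ndarray
    extreme_persons: np.ndarray  # bool flags: min/max raw score
    extreme_items: np.ndarray
    loglik: float
    n_iterations: int = 0
    persons: tuple[str, ...] = ()
    items: tuple[str, ...] = ()

    @property
    def n_categories(self) -> int:
        return len(self.tau) + 1

    def to_dict(self) -> dict:
        return {
            "persons": list(self.persons),
            "items": list(self.items),
            "theta": self.theta.tolist(),
            "delta": self.delta.tolist(),
            "tau": self.tau.tolist(),
            "se_theta": self.se_theta.tolist(),
            "se_delta": self.se_delta.tolist(),
            "extreme_persons": self.extreme_persons.astype(bool).tolist(),
            "extreme_items": self.extreme_items.astype(bool).tolist(),
            "loglik": self.loglik,
            "n_iterations": self.n_iterations,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RSMParameters":
        return cls(
            theta=np.asarray(d["theta"], float),
            delta=np.asarray(d["delta"], float),
            tau=np.asarray(d["tau"], float),
            se_theta=np.asarray(d["se_theta"], float),
            se_delta=np.asarray(d["se_delta"], float),
            extreme_persons=np.asarray(d["extreme_persons"], bool),
            extreme_items=np.asarray(d["extreme_items"], bool),
            loglik=float(d["loglik"]),
            n_iterations=int(d.get("n_iterations", 0)),
            persons=tuple(d.get("persons", ())),
            items=tuple(d.get("items", ())),
        )


def _check_finite(*arrays) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise InputError("non-finite model parameter")


def _cum_logits(tau: np.ndarray) -> np.ndarray:
    """Cumulative threshold sums s_k = sum_{j<=k} tau_j with s_0 = 0."""
    return np.concatenate([[0.0], np.cumsum(tau)])


def category_probabilities(theta, delta, tau) -> np.ndarray:
    """Category probabilities over 0..K.

    ``theta`` and ``delta`` may be scalars or broadcastable arrays; the
    returned array has the category axis last.  Probabilities are computed on
    the log scale and normalised, so they are non-negative and sum to one to
    machine precision.
    """
    tau = np.asarray(tau, dtype=float)
    theta = np.asarray(theta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    _check_finite(theta, delta, tau)
    k = np.arange(len(tau) + 1)
    x = (theta - delta)[..., None] * k - _cum_logits(tau)
    x -= x.max(axis=-1, keepdims=True)
    ex = np.exp(x)
    return ex / ex.sum(axis=-1, keepdims=True)


def expected_moments(theta, delta, tau):
    """Expected score E, variance W and fourth central moment C per cell.

    E = sum k P_k, W = sum (k-E)^2 P_k, C = sum (k-E)^4 P_k.  W and C feed
    the information-weighted fit statistics.
    """
    p = category_probabilities(theta, delta, tau)
    k = np.arange(p.shape[-1], dtype=float)
    e = (p * k).sum(axis=-1)
    d = k - e[..., None]
    w = (p * d**2).sum(axis=-1)
    c = (p * d**4).sum(axis=-1)
    return e, w, c


def _expected_matrix(theta, delta, tau):
    """E, W per person×item cell for theta (N,) and delta (L,)."""
    e, w, _ = expected_moments(
        np.asarray(theta)[:, None], np.asarray(delta)[None, :], tau
    )
    return e, w


def score_to_measure(
    raw_score: float,
    params: RSMParameters,
    items: list[str] | None = None,
    extreme_adjust: float = 0.3,
) -> tuple[float, float]:
    """Measure and SE for a raw score on an item subset (test characteristic
    curve inversion).

    Solves sum_i E_i(theta) = raw_score by monotone root-finding; extreme
    scores are pulled in by ``extreme_adjust`` score points before solving.
    SE = 1/sqrt(sum_i W_i(theta)).
    """
    if items is None:
        idx = np.arange(len(params.delta))
    else:
        idx = np.array([params.items.index(i) for i in items])
    delta = params.delta[idx]
    kmax = len(params.tau)
    max_score = kmax * len(delta)
    if not 0 <= raw_score <= max_score:
        raise InputError(f"raw score {raw_score} outside [0, {max_score}]")
    r = float(raw_score)
    if r == 0:
        r = extreme_adjust
    elif r == max_score:
        r = max_score - extreme_adjust

    def tcc(th):
        e, _, _ = expected_moments(th, delta, params.tau)
        return float(e.sum()) - r

    lo, hi = -30.0, 30.0
    theta = brentq(tcc, lo, hi, xtol=1e-10)
    _, w, _ = expected_moments(theta, delta, params.tau)
    return theta, 1.0 / np.sqrt(float(w.sum()))


def _loglik(coded: np.ma.MaskedArray, theta, delta, tau) -> float:
    p = category_probabilities(
        np.asarray(theta)[:, None], np.asarray(delta)[None, :], tau
    )
    x = coded.filled(0)
    obs = np.take_along_axis(p, x[..., None], axis=-1)[..., 0]
    ll = np.log(np.maximum(obs, 1e-300))
    return float(np.where(coded.mask, 0.0, ll).sum())


def fit_jmle(
    m: ResponseMatrix, settings: EstimationSettings | None = None
) -> RSMParameters:
    """Joint maximum-likelihood estimation of the rating-scale model.

    Alternates damped Newton-Raphson updates of theta (per person), delta
    (per item) and tau (per threshold) until the largest absolute change in
    any parameter falls below ``convergence_tol``.  Identification: mean
    delta over non-extreme items is 0 and tau sums to 0, re-applied each
    cycle.  Extreme persons/items (minimum or maximum raw score) are dropped
    from estimation and assigned measures from adjusted raw scores afterwards.
    """
    settings = settings or EstimationSettings()
    coded = m.coded()
    kmax = m.max_category

    n_obs_p = (~coded.mask).sum(axis=1)
    n_obs_i = (~coded.mask).sum(axis=0)
    raw_p = coded.filled(0).sum(axis=1)
    raw_i = coded.filled(0).sum(axis=0)
    ext_p = (raw_p == 0) | (raw_p == kmax * n_obs_p)
    ext_i = (raw_i == 0) | (raw_i == kmax * n_obs_i)

    core_p = ~ext_p
    core_i = ~ext_i
    if core_p.sum() < 2 or core_i.sum() < 2:
        raise InputError("need at least 2 non-extreme persons and 2 non-extreme items")

    sub = coded[np.ix_(core_p, core_i)]
    # every category must be seen among non-extreme cells, or its threshold
    # (and with it the scale) is unidentified
    counts = np.bincount(sub.compressed(), minlength=kmax + 1)
    unobserved = [k for k in range(kmax + 1) if counts[k] == 0]
    if unobserved:
        raise InputError(
            f"categories {unobserved} (0-based) are never observed among "
            "non-extreme persons/items; collapse categories before estimation"
        )
    nc, lc = sub.shape
    x = sub.filled(0)
    w_obs = (~sub.mask).astype(float)
    raw_n = (x * w_obs).sum(axis=1)
    raw_li = (x * w_obs).sum(axis=0)

    # PROX-style logit starting values
    frac_p = np.clip(raw_n / (kmax * w_obs.sum(axis=1)), 0.02, 0.98)
    theta = np.log(frac_p / (1 - frac_p))
    frac_i = np.clip(raw_li / (kmax * w_obs.sum(axis=0)), 0.02, 0.98)
    delta = -np.log(frac_i / (1 - frac_i))
    delta -= delta.mean()
    tau = np.zeros(kmax)

    kvec = np.arange(kmax + 1, dtype=float)
    trajectory: list[float] = []
    converged = False
    it = 0
    for it in range(1, settings.max_iterations + 1):
        p = category_probabilities(theta[:, None], delta[None, :], tau)
        e = (p * kvec).sum(axis=-1)
        w = (p * (kvec - e[..., None]) ** 2).sum(axis=-1)
        e = e * w_obs
        w = w * w_obs

        # persons: dl/dtheta = r_n - sum_i E, d2 = -sum_i W
        step_t = (raw_n - e.sum(axis=1)) / np.maximum(w.sum(axis=1), 1e-10)
        step_t = np.clip(step_t, -settings.step_cap, settings.step_cap)
        theta = theta + step_t

        p = category_probabilities(theta[:, None], delta[None, :], tau)
        e = (p * kvec).sum(axis=-1) * w_obs
        w = (p * (kvec - (p * kvec).sum(axis=-1)[..., None]) ** 2).sum(axis=-1) * w_obs

        # items: dl/ddelta = sum_n (E - x), d2 = -sum_n W
        step_d = (e.sum(axis=0) - raw_li) / np.maximum(w.sum(axis=0), 1e-10)
        step_d = np.clip(step_d, -settings.step_cap, settings.step_cap)
        delta = delta + step_d
        delta = delta - delta.mean()

        # thresholds: dl/dtau_j = sum_cells (P(X>=j) - 1{x>=j}),
        # d2 = -sum_cells P(X>=j)(1 - P(X>=j))
        p = category_probabilities(theta[:, None], delta[None, :], tau)
        step_s = np.zeros(kmax)
        for j in range(1, kmax + 1):
            pj = p[..., j:].sum(axis=-1)
            obs_ge = (x >= j).astype(float)
            grad = ((pj - obs_ge) * w_obs).sum()
            hess = (pj * (1 - pj) * w_obs).sum()
            step_s[j - 1] = grad / max(hess, 1e-10)
        step_s = np.clip(step_s, -settings.step_cap, settings.step_cap)
        tau = tau + step_s
        tau = tau - tau.mean()

        change = max(
            np.abs(step_t).max(), np.abs(step_d).max(), np.abs(step_s).max()
        )
        trajectory.append(float(change))
        if change < settings.convergence_tol:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"JMLE did not converge in {settings.max_iterations} cycles "
            f"(last change {trajectory[-1]:.2e})",
            trajectory,
        )

    if settings.bias_correction and lc > 1:
        shrink = (lc - 1) / lc
        theta = theta * shrink
        delta = delta * shrink
        delta = delta - delta.mean()

    # standard errors from the diagonal information
    p = category_probabilities(theta[:, None], delta[None, :], tau)
    w = (p * (kvec - (p * kvec).sum(axis=-1)[..., None]) ** 2).sum(axis=-1) * w_obs
    se_t = 1.0 / np.sqrt(np.maximum(w.sum(axis=1), 1e-10))
    se_d = 1.0 / np.sqrt(np.maximum(w.sum(axis=0), 1e-10))

    # expand back to the full person/item sets
    n, l = m.n_persons, m.n_items
    theta_full = np.zeros(n)
    delta_full = np.zeros(l)
    se_t_full = np.zeros(n)
    se_d_full = np.zeros(l)
    theta_full[core_p] = theta
    delta_full[core_i] = delta
    se_t_full[core_p] = se_t
    se_d_full[core_i] = se_d

    params = RSMParameters(
        theta=theta_full,
        delta=delta_full,
        tau=tau,
        se_theta=se_t_full,
        se_delta=se_d_full,
        extreme_persons=ext_p,
        extreme_items=ext_i,
        loglik=0.0,
        n_iterations=it,
        persons=m.persons,
        items=m.items,
    )

    # measures for extreme persons from adjusted raw scores
    core_items = [m.items[i] for i in np.where(core_i)[0]]
    for nidx in np.where(ext_p)[0]:
        row = coded[nidx, core_i]
        score = float(row.compressed().sum())
        th, se = score_to_measure(
            score, params, core_items, settings.extreme_adjust
        )
        theta_full[nidx] = th
        se_t_full[nidx] = se
    # extreme items: difficulty from an analogous adjusted item score
    for iidx in np.where(ext_i)[0]:
        col = coded[core_p, iidx]
        score = float(col.compressed().sum())
        n_col = col.count()
        max_score = kmax * n_col
        r = min(max(score, settings.extreme_adjust), max_score - settings.extreme_adjust)

        def icc(d):
            e_, _, _ = expected_moments(theta_full[core_p], d, tau)
            return float(e_.sum()) - r

        delta_full[iidx] = brentq(icc, -30, 30, xtol=1e-10)
        _, w_, _ = expected_moments(theta_full[core_p], delta_full[iidx], tau)
        se_d_full[iidx] = 1.0 / np.sqrt(float(w_.sum()))

    params.loglik = _loglik(coded, theta_full, delta_full, tau)
    return params
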