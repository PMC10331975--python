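import numpy as np
import pandas as pd
import pytest

import raschclimate as rc
from raschclimate.fit import FitTable
from raschclimate.rsm import EstimationSettings


def _small_fit(seed=5, n=200, l=5):
    cfg = rc.SimulationConfig(
        n_persons=n, items=tuple(f"I{i}" for i in range(l)),
        theta_sd=1.2, delta_range=(-1, 1), seed=seed,
    )
    m, _, _ = rc.simulate_responses(cfg)
    params = rc.fit_jmle(m, EstimationSettings(convergence_tol=1e-7, max_iterations=5000))
    return m, params


class TestStandardizedResiduals:
    def test_hand_computed_cell(self):
        # theta=delta, tau all 0, K=4: E=2, W = sum (k-2)^2 / 5 = 2
        vals = np.full((2, 2), 5)
        vals[1] = [1, 3]
        m = rc.ResponseMatrix(vals, ("a", "b"), ("x", "y"), 5)
        p = rc.RSMParameters(
            theta=np.zeros(2), delta=np.zeros(2), tau=np.zeros(4),
            se_theta=np.ones(2), se_delta=np.ones(2),
            extreme_persons=np.zeros(2, bool), extreme_items=np.zeros(2, bool),
            loglik=0.0, persons=("a", "b"), items=("x", "y"),
        )
        e, z, w = rc.standardized_residuals(m, p)
        assert e[0, 0] == pytest.approx(2.0)
        assert w[0, 0] == pytest.approx(2.0)
        assert z[0, 0] == pytest.approx(np.sqrt(2.0))
        assert e[1, 1] == pytest.approx(0.0)   # x = 3 hits E exactly
        assert z[1, 0] == pytest.approx(-np.sqrt(2.0))

    def test_score_equations_hold_at_jmle_solution(self):
        m, params = _small_fit()
        e, z, w = rc.standardized_residuals(m, params)
        core = ~params.extreme_persons
        col_sums = np.asarray(e)[core][:, ~params.extreme_items].sum(axis=0)
        assert np.abs(col_sums).max() < 1e-3

    def test_dimension_mismatch_rejected(self, fitted_cohort, toy_matrix):
        _, _, _, p = fitted_cohort
        with pytest.raises(rc.InputError):
            rc.standardized_residuals(toy_matrix, p)


def _direct_arithmetic_oracle(m, p):
    """Cell-by-cell spreadsheet-style infit/outfit, independent loops."""
    out = {}
    for j, item in enumerate(m.items):
        se2 = sw = so = n = 0.0
        for i in range(m.n_persons):
            if m.missing_mask[i, j] or p.extreme_persons[i]:
                continue
            probs = rc.category_probabilities(p.theta[i], p.delta[j], p.tau)
            k = np.arange(len(probs))
            e = float((probs * k).sum())
            w = float((probs * (k - e) ** 2).sum())
            x = m.values[i, j] - 1
            se2 += (x - e) ** 2
            sw += w
            so += (x - e) ** 2 / w
            n += 1
        out[item] = (se2 / sw, so / n)
    return out


class TestItemFit:
    def test_matches_direct_arithmetic_oracle(self):
        vals = np.array([[1, 2], [2, 3], [3, 4], [4, 5], [2, 2], [5, 3]])
        m = rc.ResponseMatrix(vals, tuple("abcdef"), ("x", "y"), 5)
        p = rc.RSMParameters(
            theta=np.array([-1.5, -0.5, 0.0, 1.0, -0.8, 0.9]),
            delta=np.array([0.3, -0.3]), tau=np.array([-1.0, -0.2, 0.2, 1.0]),
            se_theta=np.ones(6), se_delta=np.ones(2),
            extreme_persons=np.zeros(6, bool), extreme_items=np.zeros(2, bool),
            loglik=0.0, persons=tuple("abcdef"), items=("x", "y"),
        )
        fit = rc.item_fit(m, p)
        oracle = _direct_arithmetic_oracle(m, p)
        for item in m.items:
            assert fit["infit_mnsq"][item] == pytest.approx(oracle[item][0], abs=1e-10)
            assert fit["outfit_mnsq"][item] == pytest.approx(oracle[item][1], abs=1e-10)

    def test_null_data_mean_squares_concentrate_near_one(self, fitted_cohort):
        m, _, _, p = fitted_cohort
        fit = rc.item_fit(m, p)
        assert fit["infit_mnsq"].between(0.85, 1.15).all()
        assert abs(fit["infit_mnsq"].mean() - 1.0) < 0.05
        assert abs(fit["outfit_mnsq"].mean() - 1.0) < 0.05

    def test_uniform_random_item_shows_outfit_misfit(self):
        hits = 0
        for seed in range(12):
            cfg = rc.SimulationConfig(
                n_persons=500, items=tuple(f"I{i}" for i in range(10)),
                theta_sd=1.5, delta_range=(-1, 1), seed=seed,
            )
            m, _, _ = rc.simulate_responses(cfg)
            rng = np.random.default_rng(1000 + seed)
            vals = m.values.copy()
            vals[:, 0] = rng.integers(1, 6, size=m.n_persons)
            m2 = rc.ResponseMatrix(vals, m.persons, m.items, 5)
            p = rc.fit_jmle(m2)
            fit = rc.item_fit(m2, p)
            hits += fit["outfit_mnsq"]["I0"] > 1.3
        assert hits >= 10

    def test_wild_response_moves_outfit_more_than_infit(self, fitted_cohort):
        m, _, _, p = fitted_cohort
        base = rc.item_fit(m, p)
        easy = base.table["measure"].idxmin()
        j = m.items.index(easy)
        core = np.where(~p.extreme_persons)[0]
        target = core[np.argmax(p.theta[core])]  # far above the easy item
        vals = m.values.copy()
        vals[target, j] = 1
        m2 = rc.ResponseMatrix(vals, m.persons, m.items, 5)
        bumped = rc.item_fit(m2, p)
        d_out = bumped["outfit_mnsq"][easy] - base["outfit_mnsq"][easy]
        d_in = bumped["infit_mnsq"][easy] - base["infit_mnsq"][easy]
        assert d_out > d_in > 0

    def test_invariant_to_person_ordering(self, fitted_cohort):
        m, _, _, p = fitted_cohort
        fit1 = rc.item_fit(m, p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_persons)
        m2 = rc.ResponseMatrix(
            m.values[perm], tuple(m.persons[i] for i in perm), m.items, 5
        )
        p2 = rc.RSMParameters(
            theta=p.theta[perm], delta=p.delta, tau=p.tau,
            se_theta=p.se_theta[perm], se_delta=p.se_delta,
            extreme_persons=p.extreme_persons[perm], extreme_items=p.extreme_items,
            loglik=p.loglik, persons=m2.persons, items=p.items,
        )
        fit2 = rc.item_fit(m2, p2)
        pd.testing.assert_frame_equal(fit1.table, fit2.table)


class TestClassifyItemFit:
    @pytest.mark.parametrize(
        "infit,expected",
        [(1.42, "misfit"), (1.29, "fit"), (0.7, "fit"), (1.3, "fit"), (0.69, "misfit")],
    )
    def test_verdicts_with_closed_interval(self, infit, expected):
        df = pd.DataFrame(
            {"infit_mnsq": [infit], "infit_z": [0.0],
             "outfit_mnsq": [1.0], "outfit_z": [0.0], "n_obs": [100],
             "defined": [True]},
            index=pd.Index(["q"], name="id"),
        )
        verdict = rc.classify_item_fit(FitTable(df), rc.AnalysisConfig())
        assert verdict["q"] == expected


class TestPersonFit:
    def test_flag_requires_both_mnsq_and_z(self):
        df = pd.DataFrame(
            {
                "infit_mnsq": [1.5, 1.5, 1.2, 1.4],
                "infit_z": [2.5, 1.0, 3.0, 2.0],
                "outfit_mnsq": [1.0] * 4,
                "outfit_z": [0.0] * 4,
                "n_obs": [10] * 4,
                "defined": [True] * 4,
            },
            index=pd.Index(list("abcd"), name="id"),
        )
        flags = rc.flag_persons(FitTable(df), rc.AnalysisConfig())
        assert flags.tolist() == [True, False, False, True]
        assert rc.flag_rate(FitTable(df), rc.AnalysisConfig()) == 0.5

    def test_careless_persons_are_flagged_more_often_than_null(self):
        cfg = rc.SimulationConfig(
            n_persons=600, items=tuple(f"I{i}" for i in range(10)),
            theta_sd=1.5, delta_range=(-1, 1), careless_fraction=0.1, seed=11,
        )
        m, _, truth = rc.simulate_responses(cfg)
        p = rc.fit_jmle(m)
        pfit = rc.person_fit(m, p)
        flags = rc.flag_persons(pfit, rc.AnalysisConfig()).to_numpy()
        careless = np.zeros(m.n_persons, bool)
        careless[truth["careless_persons"]] = True
        assert flags[careless].mean() > 3 * max(flags[~careless].mean(), 0.01)
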