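import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

import raschclimate as rc
from raschclimate.io_model import InputError
from raschclimate.rsm import ConvergenceError, EstimationSettings


class TestCategoryProbabilities:
    def test_zero_thresholds_on_target_is_uniform(self):
        p = rc.category_probabilities(0.0, 0.0, np.zeros(4))
        assert np.allclose(p, 0.2, atol=1e-12)

    def test_dichotomous_symmetry(self):
        p = rc.category_probabilities(1.3, 1.3, np.zeros(1))
        assert np.allclose(p, [0.5, 0.5], atol=1e-12)

    def test_hand_evaluated_ln2_case(self):
        # numerators 2^0, 2^1, 2^2 -> (1/7, 2/7, 4/7)
        p = rc.category_probabilities(np.log(2.0), 0.0, np.zeros(2))
        assert np.allclose(p, [1 / 7, 2 / 7, 4 / 7], atol=1e-12)

    def test_non_finite_input_rejected(self):
        with pytest.raises(InputError):
            rc.category_probabilities(np.inf, 0.0, np.zeros(2))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(-8, 8), st.floats(-8, 8),
        st.lists(st.floats(-4, 4), min_size=1, max_size=6),
    )
    def test_normalization_and_positivity(self, theta, delta, tau):
        p = rc.category_probabilities(theta, delta, np.array(tau))
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12


class TestExpectedMoments:
    def test_symmetric_distribution_has_central_mean(self):
        e, w, c = rc.expected_moments(0.0, 0.0, np.zeros(4))
        assert e == pytest.approx(2.0, abs=1e-12)
        assert w > 0 and c > 0

    def test_degenerate_top_category_limit(self):
        e, w, _ = rc.expected_moments(30.0, 0.0, np.zeros(4))
        assert e == pytest.approx(4.0, abs=1e-6)
        assert w == pytest.approx(0.0, abs=1e-6)

    def test_hand_evaluated_ln2_case(self):
        e, _, _ = rc.expected_moments(np.log(2.0), 0.0, np.zeros(2))
        assert e == pytest.approx(10 / 7, abs=1e-12)

    def test_expected_score_increases_in_theta(self):
        tau = np.array([-1.0, 0.2, 0.8])
        grid = np.linspace(-5, 5, 101)
        e, _, _ = rc.expected_moments(grid, 0.0, tau)
        assert np.all(np.diff(e) > 0)


def _profile_grid_oracle(x, coarse_step=0.2, span=2.0):
    """Grid-search maximizer of the joint log-likelihood for a 4×3 matrix
    with 3 categories: free parameters (d1, d2, t1) under mean(delta)=0 and
    sum(tau)=0; persons profiled out on a 0.01-logit grid.  Coarse pass then
    two refinements down to a 0.01-logit grid."""
    tgrid = np.arange(-4, 4.0001, 0.01)
    n, l = x.shape

    def ll_of(d1, d2, t1):
        delta = np.array([d1, d2, -d1 - d2])
        tau = np.array([t1, -t1])
        p = rc.category_probabilities(tgrid[:, None], delta[None, :], tau)
        lp = np.log(np.maximum(p, 1e-300))
        total = 0.0
        for row in x:
            total += lp[:, np.arange(l), row].sum(axis=1).max()
        return total

    centre, step = (0.0, 0.0, 0.0), coarse_step
    best = None
    for step, span_ in [(coarse_step, span), (0.05, 0.25), (0.01, 0.06)]:
        axes = [np.arange(c - span_, c + span_ + 1e-9, step) for c in centre]
        best = None
        for d1 in axes[0]:
            for d2 in axes[1]:
                for t1 in axes[2]:
                    ll = ll_of(d1, d2, t1)
                    if best is None or ll > best[0]:
                        best = (ll, d1, d2, t1)
        centre = best[1:]
    _, d1, d2, t1 = best
    return np.array([d1, d2, -d1 - d2]), np.array([t1, -t1])


class TestJMLE:
    def test_matches_grid_search_oracle_on_toy_matrix(self, toy_matrix, tight_settings):
        params = rc.fit_jmle(toy_matrix, tight_settings)
        delta_o, tau_o = _profile_grid_oracle(toy_matrix.values - 1)
        assert np.abs(params.delta - delta_o).max() < 0.02
        assert np.abs(params.tau - tau_o).max() < 0.02

    def test_identification_constraints_hold(self, fitted_cohort):
        _, _, _, p = fitted_cohort
        core = ~p.extreme_items
        assert abs(p.delta[core].mean()) < 1e-6
        assert abs(p.tau.sum()) < 1e-6
        assert np.all(p.se_theta[~p.extreme_persons] > 0)
        assert np.all(p.se_delta[core] > 0)

    def test_parameter_recovery_from_known_truth(self, model_true_cohort):
        m, _, truth = model_true_cohort
        params = rc.fit_jmle(m, EstimationSettings(bias_correction=True))
        core = ~params.extreme_items
        r = np.corrcoef(truth["delta"][core], params.delta[core])[0, 1]
        rmse = float(np.sqrt(np.mean((truth["delta"][core] - params.delta[core]) ** 2)))
        assert r >= 0.99
        assert rmse <= 0.12

    def test_permutation_equivariance(self, toy_matrix, tight_settings):
        p1 = rc.fit_jmle(toy_matrix, tight_settings)
        rng = np.random.default_rng(3)
        pp = rng.permutation(toy_matrix.n_persons)
        ip = rng.permutation(toy_matrix.n_items)
        m2 = rc.ResponseMatrix(
            toy_matrix.values[np.ix_(pp, ip)],
            tuple(toy_matrix.persons[i] for i in pp),
            tuple(toy_matrix.items[j] for j in ip),
            toy_matrix.n_categories,
        )
        p2 = rc.fit_jmle(m2, tight_settings)
        assert np.allclose(p2.theta, p1.theta[pp], atol=1e-5)
        assert np.allclose(p2.delta, p1.delta[ip], atol=1e-5)

    def test_recovery_improves_with_sample_size(self):
        # averaged over matched seed pairs, larger cohorts recover delta better
        def rmse_at(n, seed):
            cfg = rc.SimulationConfig(
                n_persons=n, items=tuple(f"I{i}" for i in range(10)),
                theta_sd=1.5, delta_range=(-1.5, 1.5), seed=seed,
            )
            m, _, truth = rc.simulate_responses(cfg)
            p = rc.fit_jmle(m)
            core = ~p.extreme_items
            return np.sqrt(np.mean((truth["delta"][core] - p.delta[core]) ** 2))

        small = np.mean([rmse_at(200, s) for s in range(20)])
        large = np.mean([rmse_at(2000, s) for s in range(20)])
        assert large < small

    def test_unobserved_interior_category_raises(self):
        vals = np.array([[1, 5], [5, 1], [1, 5], [5, 5]])  # categories 2..4 unseen
        m = rc.ResponseMatrix(vals, tuple("abcd"), ("x", "y"), 5)
        with pytest.raises(InputError, match="collapse"):
            rc.fit_jmle(m)

    def test_non_convergence_reports_trajectory(self, toy_matrix):
        with pytest.raises(ConvergenceError) as err:
            rc.fit_jmle(toy_matrix, EstimationSettings(max_iterations=2, convergence_tol=1e-12))
        assert len(err.value.trajectory) == 2

    def test_extreme_persons_get_finite_measures(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(2, 5, size=(30, 5))
        vals[0] = 5  # ceiling person
        vals[1] = 1  # floor person
        vals[2:5, 0] = 1  # keep every category observed among non-extremes
        vals[5:8, 1] = 2
        vals[8:11, 2] = 5
        m = rc.ResponseMatrix(vals, tuple(f"p{i}" for i in range(30)),
                              tuple(f"q{j}" for j in range(5)), 5)
        p = rc.fit_jmle(m, EstimationSettings(max_iterations=1000))
        assert p.extreme_persons[0] and p.extreme_persons[1]
        assert np.isfinite(p.theta).all() and np.isfinite(p.se_theta).all()
        assert p.theta[0] > p.theta[1]

    def test_serialization_round_trip(self, fitted_cohort):
        _, _, _, p = fitted_cohort
        back = rc.RSMParameters.from_dict(p.to_dict())
        assert np.allclose(back.theta, p.theta)
        assert np.allclose(back.tau, p.tau)
        assert back.items == p.items


class TestScoreToMeasure:
    def test_midpoint_of_symmetric_instrument_maps_to_zero(self, fitted_cohort):
        _, _, _, p = fitted_cohort
        sym = rc.RSMParameters(
            theta=p.theta, delta=np.zeros(4), tau=np.array([-1.0, -0.3, 0.3, 1.0]),
            se_theta=p.se_theta, se_delta=np.ones(4),
            extreme_persons=p.extreme_persons, extreme_items=np.zeros(4, bool),
            loglik=0.0, items=("a", "b", "c", "d"),
        )
        measure, se = rc.score_to_measure(8, sym)  # midpoint of 0..16
        assert measure == pytest.approx(0.0, abs=1e-8)
        assert se > 0

    def test_measures_strictly_increase_with_raw_score(self, fitted_cohort):
        _, _, _, p = fitted_cohort
        max_score = 4 * len(p.delta)
        measures = [rc.score_to_measure(r, p)[0] for r in range(max_score + 1)]
        assert np.all(np.diff(measures) > 0)

    def test_matches_bisection_oracle(self, fitted_cohort):
        _, _, _, p = fitted_cohort
        target = 25.0

        def f(th):
            e, _, _ = rc.expected_moments(th, p.delta, p.tau)
            return float(e.sum()) - target

        oracle = brentq(f, -30, 30, xtol=1e-6)
        measure, _ = rc.score_to_measure(25, p)
        assert measure == pytest.approx(oracle, abs=1e-6)

    def test_out_of_range_score_rejected(self, fitted_cohort):
        _, _, _, p = fitted_cohort
        with pytest.raises(InputError):
            rc.score_to_measure(4 * len(p.delta) + 1, p)
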