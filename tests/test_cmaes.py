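import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ureafit import cmaes
from ureafit.cmaes import EvolutionState, ObjectiveSpec, StrategyParameters


def sphere(x):
    return float(x @ x)


BOX = np.array([[-100.0, 100.0]] * 6)


class TestDefaultParameters:
    def test_dimension_six_constants(self):
        p = cmaes.default_parameters(6)
        assert (p.lam, p.mu) == (9, 4)
        assert p.mu_w == pytest.approx(2.600, abs=1e-3)
        assert p.c_sigma == pytest.approx(2 / 3, abs=1e-4)
        assert p.c_c == pytest.approx(2 / 3, abs=1e-4)
        assert p.c_1 == pytest.approx(2 / 36, abs=1e-4)
        assert p.c_mu == pytest.approx(p.mu_w / 36, abs=1e-4)
        assert p.c_1 + p.c_mu <= 1
        assert p.chi_n == pytest.approx(2.3507, abs=1e-4)
        assert p.d_sigma == pytest.approx(1 + math.sqrt(p.mu_w / 6), abs=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(n=st.integers(2, 20), lam=st.integers(4, 40))
    def test_weight_identities(self, n, lam):
        p = cmaes.default_parameters(n, lam=lam)
        assert np.sum(p.weights) == pytest.approx(1.0, abs=1e-12)
        assert p.mu_w == pytest.approx(1.0 / np.sum(p.weights**2), rel=1e-12)
        assert 1.0 <= p.mu_w <= p.mu
        assert np.all(np.diff(p.weights) <= 0) and np.all(p.weights > 0)
        assert p.c_1 + p.c_mu <= 1

    def test_invalid_dimension(self):
        with pytest.raises(ValueError):
            cmaes.default_parameters(0)


def _custom_params(lam, mu, weights, n=2, **rates):
    base = cmaes.default_parameters(n, lam=lam, mu=mu)
    kw = dict(
        n=n, lam=lam, mu=mu, weights=np.asarray(weights, dtype=float),
        mu_w=1.0 / float(np.sum(np.asarray(weights) ** 2)),
        c_sigma=base.c_sigma, d_sigma=base.d_sigma, c_c=base.c_c,
        c_1=base.c_1, c_mu=base.c_mu, chi_n=base.chi_n,
    )
    kw.update(rates)
    return StrategyParameters(**kw)


class TestSampling:
    def test_zero_step_size_collapses_to_mean(self):
        p = cmaes.default_parameters(3)
        state = EvolutionState(m=np.array([1.0, 2.0, 3.0]), sigma=0.0,
                               C=np.eye(3), p_sigma=np.zeros(3), p_c=np.zeros(3))
        X, _ = cmaes.sample_population(state, p, np.random.default_rng(0))
        assert np.all(X == state.m)

    def test_seeded_reproducibility(self):
        p = cmaes.default_parameters(4)
        for _ in range(2):
            state = EvolutionState.initial(np.zeros(4), 1.0)
            X1, Y1 = cmaes.sample_population(state, p, np.random.default_rng(7))
            X2, Y2 = cmaes.sample_population(state, p, np.random.default_rng(7))
            np.testing.assert_array_equal(X1, X2)
            np.testing.assert_array_equal(Y1, Y2)

    def test_empirical_covariance_matches_request(self):
        p = cmaes.default_parameters(2, lam=10)
        state = EvolutionState.initial(np.zeros(2), 1.0)
        state.C = np.diag([1.0, 4.0])
        rng = np.random.default_rng(11)
        ys = []
        for _ in range(math.ceil(100_000 / p.lam)):
            _, Y = cmaes.sample_population(state, p, rng)
            ys.append(Y)
        emp = np.cov(np.vstack(ys).T)
        assert emp[0, 0] == pytest.approx(1.0, rel=0.05)
        assert emp[1, 1] == pytest.approx(4.0, rel=0.05)
        assert abs(emp[0, 1]) < 0.05

    def test_bounds_respected(self):
        p = cmaes.default_parameters(2)
        state = EvolutionState.initial(np.array([99.0, 99.0]), 10.0)
        bounds = np.array([[-100.0, 100.0]] * 2)
        for seed in range(5):
            X, Y = cmaes.sample_population(state, p, np.random.default_rng(seed), bounds)
            assert np.all(X >= -100) and np.all(X <= 100)
            # y stays consistent with x even after clamping
            np.testing.assert_allclose(state.m + state.sigma * Y, X, atol=1e-12)


class TestSelection:
    def test_single_parent_takes_best_step(self):
        p = _custom_params(3, 1, [1.0])
        Y = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 3.0]])
        order, y_bar = cmaes.rank_and_select(Y, [5.0, 1.0, 9.0], p)
        assert order[0] == 1
        np.testing.assert_array_equal(y_bar, Y[1])

    def test_stable_tie_break_by_index(self):
        p = _custom_params(4, 2, [0.7, 0.3])
        Y = np.arange(8.0).reshape(4, 2)
        order, y_bar = cmaes.rank_and_select(Y, [1.0, 1.0, 1.0, 1.0], p)
        assert list(order[:2]) == [0, 1]
        np.testing.assert_allclose(y_bar, 0.7 * Y[0] + 0.3 * Y[1])

    def test_weighted_step_from_hand_sorted_values(self):
        p = _custom_params(3, 2, [0.75, 0.25])
        Y = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 2.0]])
        _, y_bar = cmaes.rank_and_select(Y, [2.0, 0.0, 1.0], p)
        np.testing.assert_allclose(y_bar, 0.75 * Y[1] + 0.25 * Y[2])

    def test_nan_value_names_candidate(self):
        p = _custom_params(3, 2, [0.75, 0.25])
        with pytest.raises(ValueError, match="candidate 1"):
            cmaes.rank_and_select(np.zeros((3, 2)), [1.0, np.nan, 2.0], p)


class TestUpdates:
    def test_mean_shift(self):
        p = cmaes.default_parameters(2)
        state = EvolutionState.initial([1.0, 1.0], 2.0)
        cmaes.update_mean(state, np.array([1.0, 0.0]), p)
        np.testing.assert_array_equal(state.m, [3.0, 1.0])
        cmaes.update_mean(state, np.zeros(2), p)
        np.testing.assert_array_equal(state.m, [3.0, 1.0])

    def test_step_size_fixed_point_at_chi_n(self):
        # engineered so the post-update path norm equals chi_n exactly
        p = cmaes.default_parameters(2)
        state = EvolutionState.initial(np.zeros(2), 1.5)
        cs = p.c_sigma
        scale = p.chi_n / math.sqrt(cs * (2 - cs) * p.mu_w)
        y_bar = np.array([scale, 0.0])
        cmaes.update_step_size(state, y_bar, p)
        assert np.linalg.norm(state.p_sigma) == pytest.approx(p.chi_n, rel=1e-12)
        assert state.sigma == pytest.approx(1.5, rel=1e-12)

    def test_zero_step_shrinks_sigma(self):
        p = cmaes.default_parameters(3)
        state = EvolutionState.initial(np.zeros(3), 1.0)
        cmaes.update_step_size(state, np.zeros(3), p)
        np.testing.assert_array_equal(state.p_sigma, np.zeros(3))
        assert state.sigma == pytest.approx(math.exp(-p.c_sigma / p.d_sigma), rel=1e-12)

    def test_inverse_sqrt_of_scalar_covariance(self):
        # C = 4I gives C^(-1/2) y = y/2; verify through the path update
        p = cmaes.default_parameters(2)
        state = EvolutionState.initial(np.zeros(2), 1.0)
        state.C = 4.0 * np.eye(2)
        y_bar = np.array([1.0, -2.0])
        cmaes.update_step_size(state, y_bar, p)
        cs = p.c_sigma
        expected = math.sqrt(cs * (2 - cs) * p.mu_w) * y_bar / 2.0
        np.testing.assert_allclose(state.p_sigma, expected, rtol=1e-12)

    def test_covariance_frozen_when_learning_rates_zero(self):
        p = _custom_params(4, 2, [0.6, 0.4], c_1=0.0, c_mu=0.0, c_c=0.5)
        state = EvolutionState.initial(np.zeros(2), 1.0)
        C0 = state.C.copy()
        cmaes.update_covariance(state, np.array([1.0, 1.0]), np.ones((2, 2)), p)
        np.testing.assert_array_equal(state.C, C0)

    def test_covariance_shrinks_without_signal(self):
        p = cmaes.default_parameters(2)
        state = EvolutionState.initial(np.zeros(2), 1.0)
        cmaes.update_covariance(state, np.zeros(2), np.zeros((p.mu, 2)), p)
        np.testing.assert_allclose(
            state.C, (1 - p.c_1 - p.c_mu) * np.eye(2), rtol=1e-12
        )

    def test_rank_mu_outer_product_sum(self):
        p = _custom_params(4, 2, [0.6, 0.4], c_1=0.0, c_mu=1.0, c_c=0.5)
        state = EvolutionState.initial(np.zeros(2), 1.0)
        state.p_c = np.zeros(2)
        y_sel = np.eye(2)  # unit axes
        cmaes.update_covariance(state, np.zeros(2), y_sel, p)
        np.testing.assert_allclose(state.C, np.diag([0.6, 0.4]), atol=1e-12)

    def test_covariance_stays_spd_on_sphere(self):
        p = cmaes.default_parameters(4)
        state = EvolutionState.initial(np.full(4, 10.0), 5.0)
        rng = np.random.default_rng(3)
        for _ in range(500):
            X, Y = cmaes.sample_population(state, p, rng)
            order, y_bar = cmaes.rank_and_select(Y, [sphere(x) for x in X], p)
            cmaes.update_mean(state, y_bar, p)
            cmaes.update_step_size(state, y_bar, p)
            cmaes.update_covariance(state, y_bar, Y[order[: p.mu]], p)
            assert np.max(np.abs(state.C - state.C.T)) <= 1e-10
            assert np.min(np.linalg.eigvalsh(state.C)) > 0


class TestMinimize:
    def test_sphere_converges_from_far_start(self):
        spec = ObjectiveSpec(objective=sphere, bounds=BOX, budget=20_000)
        res = cmaes.minimize(spec, seed=1, m0=[50.0] * 6, sigma0=50.0)
        assert res.fun < 1e-8
        best = [t["best_value"] for t in res.trace]
        assert np.all(np.diff(best) <= 0)

    def test_constant_objective_returns_it_and_stagnates(self):
        spec = ObjectiveSpec(objective=lambda x: 3.5, bounds=BOX, budget=50_000)
        res = cmaes.minimize(spec, seed=0)
        assert res.fun == 3.5
        assert res.stop_reason == "stagnation"

    def test_seeded_determinism_bit_identical(self):
        spec = ObjectiveSpec(objective=sphere, bounds=BOX, budget=3_000)
        r1 = cmaes.minimize(spec, seed=9)
        r2 = cmaes.minimize(spec, seed=9)
        np.testing.assert_array_equal(r1.x, r2.x)
        assert r1.fun == r2.fun
        assert r1.trace == r2.trace

    def test_translation_invariance(self):
        b = np.full(6, 3.0)
        spec0 = ObjectiveSpec(objective=sphere, bounds=BOX, budget=4_000)
        spec1 = ObjectiveSpec(
            objective=lambda x: sphere(x - b),
            bounds=BOX + b[:, None],
            budget=4_000,
        )
        r0 = cmaes.minimize(spec0, seed=5, m0=np.full(6, 20.0), sigma0=10.0)
        r1 = cmaes.minimize(spec1, seed=5, m0=np.full(6, 20.0) + b, sigma0=10.0)
        np.testing.assert_allclose(r1.x - b, r0.x, atol=1e-9)
        assert r1.fun == pytest.approx(r0.fun, abs=1e-12)

    def test_scale_invariance(self):
        s = 4.0  # power of two keeps the rescaling exact in floating point
        spec0 = ObjectiveSpec(objective=sphere, bounds=BOX, budget=4_000)
        spec1 = ObjectiveSpec(
            objective=lambda x: sphere(x / s), bounds=BOX * s, budget=4_000
        )
        r0 = cmaes.minimize(spec0, seed=5, m0=np.full(6, 20.0), sigma0=10.0)
        r1 = cmaes.minimize(spec1, seed=5, m0=np.full(6, 20.0 * s), sigma0=10.0 * s)
        np.testing.assert_allclose(r1.x / s, r0.x, atol=1e-9)

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveSpec(objective=sphere, bounds=BOX, budget=0)
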