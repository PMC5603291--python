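"""EM update algebra: hand-computed steps, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alphaem.fixtures import make_toy
from alphaem.projector import SystemMatrix
from alphaem.recon import (AlphaEM, ReconConfig, additive_form_update,
                           alpha_em_update, mlem_update, noise_weights,
                           poisson_loglikelihood, reconstruct, step_size_field,
                           weighted_objective)


class TestMlemUpdate:
    def test_identity_system_one_step_solution(self):
        toy = make_toy("identity")
        x1 = mlem_update(np.ones(2), np.array([3.0, 5.0]), toy.operator)
        assert np.allclose(x1, [3.0, 5.0], rtol=1e-14)

    def test_consistent_data_is_fixed_point(self):
        toy = make_toy("random", seed=4)
        x1 = mlem_update(toy.x_true, toy.p, toy.operator)
        assert np.allclose(x1, toy.x_true, rtol=1e-12)

    def test_hand_computed_two_ray_average(self):
        # 1 pixel seen by two unit-weight rays; x0 = 1 so q = (1, 1):
        # x1 = 1 * (2/1 + 4/1) / (1 + 1) = 3
        sm = SystemMatrix.from_matrix(np.array([[1.0], [1.0]]))
        x1 = mlem_update(np.array([1.0]), np.array([2.0, 4.0]), sm)
        assert x1[0] == pytest.approx(3.0, rel=1e-15)


class TestAlphaEmUpdate:
    def test_alpha_one_is_mlem_bitwise(self):
        toy = make_toy("random", seed=2, noisy=True)
        x = np.abs(np.random.default_rng(0).normal(2.0, 0.5, 4))
        a = mlem_update(x, toy.p, toy.operator)
        b = alpha_em_update(x, toy.p, toy.operator, alpha=1.0)
        assert np.array_equal(a, b)

    def test_hand_computed_alpha_two(self):
        # single pixel, one ray of weight 2: x=1 -> q=2; p=4, alpha=2:
        # x' = 1 * [2 * 4/4] / [2 * 2/4] = 2
        sm = SystemMatrix.from_matrix(np.array([[2.0]]))
        x1 = alpha_em_update(np.array([1.0]), np.array([4.0]), sm, alpha=2.0)
        assert x1[0] == pytest.approx(2.0, rel=1e-15)

    @pytest.mark.parametrize("alpha", [0.3, 1.0, 1.7, 3.0])
    def test_consistent_data_fixed_point_any_alpha(self, alpha):
        toy = make_toy("random", seed=8)
        x1 = alpha_em_update(toy.x_true, toy.p, toy.operator, alpha)
        assert np.allclose(x1, toy.x_true, rtol=1e-12)

    def test_alpha_validation(self):
        toy = make_toy("identity")
        with pytest.raises(ValueError):
            alpha_em_update(np.ones(2), toy.p, toy.operator, alpha=0.0)
        with pytest.raises(ValueError):
            alpha_em_update(np.ones(2), toy.p, toy.operator, alpha=6.0)


class TestAdditiveFormOracle:
    @pytest.mark.parametrize("seed", range(20))
    def test_equivalent_to_multiplicative(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0.05, 1.0, size=(6, 4))
        sm = SystemMatrix.from_matrix(A)
        x = rng.uniform(0.2, 3.0, 4)
        p = rng.uniform(0.0, 8.0, 6)
        alpha = float(rng.uniform(0.1, 3.0))
        mul = alpha_em_update(x, p, sm, alpha)
        add = additive_form_update(x, p, sm, alpha)
        assert np.max(np.abs(add - mul)) <= 1e-10 * np.max(np.abs(mul))

    def test_consistent_data_zero_correction(self):
        toy = make_toy("random", seed=1)
        x1 = additive_form_update(toy.x_true, toy.p, toy.operator, alpha=1.4)
        assert np.allclose(x1, toy.x_true, rtol=1e-12)


class TestObjectivesAndDiagnostics:
    def test_weighted_objective_basics(self):
        sm = SystemMatrix.from_matrix(np.array([[1.0]]))
        assert weighted_objective(np.array([5.0]), np.array([5.0]), sm,
                                  np.array([2.0])) == 0.0
        # single ray, residual 3, unit weight -> 9
        assert weighted_objective(np.array([1.0]), np.array([4.0]), sm,
                                  np.array([1.0])) == pytest.approx(9.0)
        with pytest.raises(ValueError):
            weighted_objective(np.array([1.0]), np.array([1.0]), sm,
                               np.array([-1.0]))

    def test_loglik_maximized_at_consistent_q(self):
        toy = make_toy("random", seed=3)
        sm = toy.operator
        base = poisson_loglikelihood(toy.x_true, toy.p, sm)
        rng = np.random.default_rng(0)
        for _ in range(10):
            pert = toy.x_true * rng.uniform(0.6, 1.5, toy.x_true.size)
            assert poisson_loglikelihood(pert, toy.p, sm) <= base + 1e-12

    def test_loglik_all_zero_counts(self):
        toy = make_toy("random", seed=3)
        x = np.full(4, 0.7)
        q = np.asarray(toy.operator.A @ x)
        assert poisson_loglikelihood(x, np.zeros(6), toy.operator) == \
            pytest.approx(-q.sum())

    def test_noise_weights_and_step_size(self):
        toy = make_toy("random", seed=5)
        q = np.asarray(toy.operator.A @ toy.x_true)
        W = noise_weights(q, alpha=2.0)
        assert np.allclose(W, 1.0 / q**2)
        step = step_size_field(toy.x_true, toy.operator, alpha=1.0)
        den = np.asarray(toy.operator.A.T @ np.ones(6))
        assert np.allclose(step, toy.x_true / den)


class TestInvariants:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), alpha=st.floats(0.1, 3.0))
    def test_iterates_stay_nonnegative(self, seed, alpha):
        rng = np.random.default_rng(seed)
        sm = SystemMatrix.from_matrix(rng.uniform(0.01, 1.0, size=(8, 5)))
        p = rng.poisson(rng.uniform(0.0, 20.0, 8)).astype(float)
        x = rng.uniform(0.1, 5.0, 5)
        for _ in range(5):
            x = alpha_em_update(x, p, sm, alpha)
            assert np.all(x >= 0.0)

    def test_mlem_preserves_total_counts(self):
        toy = make_toy("random", seed=6, noisy=True)
        x = np.full(4, 2.0)
        for _ in range(30):
            x = mlem_update(x, toy.p, toy.operator)
            q = np.asarray(toy.operator.A @ x)
            assert q.sum() == pytest.approx(toy.p.sum(), rel=1e-12)

    def test_count_preservation_fails_off_poisson_weighting(self):
        """alpha != 1 deliberately breaks the count-preservation property."""
        toy = make_toy("random", seed=6, noisy=True)
        x = np.full(4, 2.0)
        for _ in range(5):
            x = alpha_em_update(x, toy.p, toy.operator, alpha=2.0)
        q = np.asarray(toy.operator.A @ x)
        assert abs(q.sum() - toy.p.sum()) > 1e-6 * toy.p.sum()

    def test_mlem_loglik_nondecreasing(self):
        toy = make_toy("random", seed=7, noisy=True)
        x = np.full(4, 1.5)
        prev = poisson_loglikelihood(x, toy.p, toy.operator)
        for _ in range(50):
            x = mlem_update(x, toy.p, toy.operator)
            cur = poisson_loglikelihood(x, toy.p, toy.operator)
            assert cur >= prev - 1e-9 * abs(prev)
            prev = cur


class TestModelAndResults:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            ReconConfig(alpha=-1.0)
        with pytest.raises(ValueError):
            ReconConfig(init_value=0.0)

    def test_zero_iterations_keeps_initial_image(self):
        toy = make_toy("random", seed=1)
        res = reconstruct(toy.p, toy.operator, ReconConfig(max_iterations=0))
        assert res.n_iterations == 0
        assert res.best_iteration is None

    def test_initialization_matches_measured_totals(self):
        toy = make_toy("random", seed=2, noisy=True)
        x0 = AlphaEM(toy.p, toy.operator).initial_image()
        q0 = np.asarray(toy.operator.A @ x0)
        assert q0.sum() == pytest.approx(toy.p.sum(), rel=1e-12)

    def test_consistent_data_drives_fidelity_down(self):
        toy = make_toy("random", seed=9)
        res = reconstruct(toy.p, toy.operator,
                          ReconConfig(alpha=1.0, max_iterations=500))
        f = res.trace["fidelity"]
        assert f.iloc[-1] < 1e-10 * f.iloc[1]

    def test_reconstruct_equals_manual_iteration_bitwise(self):
        toy = make_toy("random", seed=3, noisy=True)
        res = reconstruct(toy.p, toy.operator,
                          ReconConfig(alpha=1.0, max_iterations=10))
        x = AlphaEM(toy.p, toy.operator).initial_image()
        for _ in range(10):
            x = mlem_update(x, toy.p, toy.operator)
        assert np.array_equal(res.image, x)

    def test_trace_and_summary(self):
        toy = make_toy("random", seed=3, noisy=True)
        res = reconstruct(toy.p, toy.operator,
                          ReconConfig(alpha=1.3, max_iterations=5),
                          store_images=True)
        assert set(res.trace.columns) >= {"fidelity", "loglik", "objective",
                                          "total_counts"}
        assert sorted(res.images) == list(range(6))
        assert "alpha:              1.3" in res.summary()
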