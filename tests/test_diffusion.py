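"""Forward process, single-step inversion, and the iterative reverse chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sssdiff import (FunctionHandle, forward_diffuse, iterative_sample,
                     make_linear_schedule, make_schedule, reverse_step,
                     single_step_denoise)


class TestLinearSchedule:
    def test_paper_endpoints(self, paper_schedule):
        s = paper_schedule
        assert s.beta[0] == pytest.approx(1e-4)
        assert s.beta[-1] == pytest.approx(0.02)
        assert s.alpha[0] == pytest.approx(0.9999)

    def test_single_step_chain(self):
        s = make_linear_schedule(1, 0.5, 0.5)
        assert s.beta.tolist() == [0.5]
        assert s.alpha_bar.tolist() == [0.5]

    def test_hand_cumulative_product(self):
        s = make_linear_schedule(3, 0.1, 0.3)
        np.testing.assert_allclose(s.beta, [0.1, 0.2, 0.3])
        np.testing.assert_allclose(s.alpha_bar, [0.9, 0.72, 0.504])

    def test_signal_destroyed_at_chain_end(self, paper_schedule):
        # near-total signal destruction by t=T
        assert paper_schedule.alpha_bar[-1] < 0.01
        assert np.all(np.diff(paper_schedule.alpha_bar) < 0)

    @pytest.mark.parametrize("T,b0,b1", [(0, 0.1, 0.2), (10, 0.0, 0.2),
                                         (10, 0.3, 0.2), (10, 0.1, 1.0)])
    def test_invalid_parameters_rejected(self, T, b0, b1):
        with pytest.raises(ValueError):
            make_linear_schedule(T, b0, b1)

    def test_cosine_reserved(self):
        with pytest.raises(NotImplementedError):
            make_schedule("cosine", 10)


class TestForwardDiffuse:
    def test_zero_noise_scales_signal(self, paper_schedule, rng):
        x0 = rng.uniform(-1, 1, (16, 16))
        out = forward_diffuse(x0, np.zeros_like(x0), 300, paper_schedule)
        np.testing.assert_allclose(
            out.x_t, np.sqrt(paper_schedule.abar(300)) * x0, atol=1e-12)

    def test_scalar_arithmetic(self):
        # abar = 0.25 at t=2 of this 2-step chain: alpha = (0.5, 0.5)
        s = make_linear_schedule(2, 0.5, 0.5)
        out = forward_diffuse(np.ones((4, 4)), np.ones((4, 4)), 2, s)
        np.testing.assert_allclose(out.x_t, 0.5 + np.sqrt(0.75), atol=1e-12)

    def test_marginal_variance(self, paper_schedule, rng):
        # Var(x_t | x0=0) = 1 - abar_t, Monte-Carlo over >= 1e4 draws
        t = 500
        draws = rng.standard_normal((100, 10, 10))  # 1e4 scalar draws
        xt = np.stack([forward_diffuse(np.zeros((10, 10)), e, t, paper_schedule).x_t
                       for e in draws])
        target = 1 - paper_schedule.abar(t)
        assert xt.var() == pytest.approx(target, rel=0.05)

    def test_shape_and_range_errors(self, paper_schedule):
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros((4, 4)), np.zeros((4, 5)), 10, paper_schedule)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros((4, 4)), np.zeros((4, 4)), 0, paper_schedule)
        with pytest.raises(ValueError):
            forward_diffuse(np.zeros((4, 4)), np.zeros((4, 4)), 1001, paper_schedule)


class TestSingleStepDenoise:
    def test_exact_inversion_of_true_noise(self, paper_schedule, rng):
        x0 = rng.uniform(-1, 1, (32, 32))
        eps = rng.standard_normal((32, 32))
        for t in (1, 250, 400, 1000):
            x_t = forward_diffuse(x0, eps, t, paper_schedule).x_t
            x0_hat = single_step_denoise(x_t, eps, t, paper_schedule, clip=None)
            assert np.abs(x0_hat - x0).max() < 1e-5

    def test_zero_prediction_rescales(self, paper_schedule):
        x_t = np.full((4, 4), 0.3)
        out = single_step_denoise(x_t, np.zeros_like(x_t), 100, paper_schedule,
                                  clip=None)
        np.testing.assert_allclose(out, 0.3 / np.sqrt(paper_schedule.abar(100)))

    def test_scalar_inverts_forward_example(self):
        s = make_linear_schedule(2, 0.5, 0.5)  # abar_2 = 0.25
        x_t = np.full((4, 4), 0.5 + np.sqrt(0.75))
        out = single_step_denoise(x_t, np.ones((4, 4)), 2, s, clip=None)
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_clipping_bounds_output(self, paper_schedule):
        x_t = np.full((4, 4), 5.0)
        out = single_step_denoise(x_t, np.zeros_like(x_t), 900, paper_schedule)
        assert out.max() <= 1.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(t=st.integers(1, 1000), seed=st.integers(0, 2 ** 20))
    def test_inversion_identity_property(self, paper_schedule, t, seed):
        r = np.random.default_rng(seed)
        x0 = r.uniform(-1, 1, (8, 8))
        eps = r.standard_normal((8, 8))
        x_t = forward_diffuse(x0, eps, t, paper_schedule).x_t
        assert np.abs(single_step_denoise(x_t, eps, t, paper_schedule, clip=None)
                      - x0).max() < 1e-5


class TestReverseStep:
    def test_small_beta_is_near_identity(self):
        s = make_linear_schedule(10, 1e-8, 1e-7)
        x_t = np.full((4, 4), 0.7)
        out = reverse_step(x_t, np.zeros_like(x_t), np.zeros_like(x_t), 5, s)
        np.testing.assert_allclose(out, x_t, atol=1e-6)

    def test_scalar_arithmetic(self):
        # beta=0.02, alpha=0.98, abar=0.25 at t=2 of a hand-built table
        from sssdiff import ScheduleTable
        s = ScheduleTable(T=2, beta=np.array([0.5, 0.02]),
                          alpha=np.array([0.5, 0.98]),
                          alpha_bar=np.array([0.5, 0.25]))
        out = reverse_step(np.ones((3, 3)), np.ones((3, 3)), np.zeros((3, 3)), 2, s)
        expected = (1 - 0.02 / np.sqrt(0.75)) / np.sqrt(0.98)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert expected == pytest.approx(0.9869, abs=1e-4)

    def test_noise_injection_is_seeded(self, paper_schedule):
        x_t = np.zeros((8, 8))
        eps_hat = np.zeros_like(x_t)
        z = np.random.default_rng(5).standard_normal(x_t.shape)
        a = reverse_step(x_t, eps_hat, z, 500, paper_schedule)
        b = reverse_step(x_t, eps_hat, z, 500, paper_schedule)
        np.testing.assert_array_equal(a, b)


class TestIterativeSample:
    def test_lambda_zero_returns_input(self, paper_schedule):
        calls = FunctionHandle(lambda x, t: np.zeros_like(x))
        x = np.full((8, 8), 0.25)
        out = iterative_sample(x, 0, calls, paper_schedule)
        np.testing.assert_array_equal(out, x)
        assert calls.eval_counter == 0

    def test_evaluation_count_matches_lambda(self, paper_schedule):
        calls = FunctionHandle(lambda x, t: np.zeros_like(x))
        iterative_sample(np.zeros((8, 8)), 400, calls, paper_schedule,
                         deterministic=True)
        assert calls.eval_counter == 400

    def test_lambda_beyond_chain_rejected(self, paper_schedule):
        with pytest.raises(ValueError):
            iterative_sample(np.zeros((4, 4)), 1001,
                             FunctionHandle(lambda x, t: x), paper_schedule)

    def test_oracle_chain_recovers_constant_image(self, paper_schedule):
        """Deterministic chain with a marginal-consistent oracle predictor,
        cross-checked against an independently coded scalar recursion."""
        c, e, lam = 0.5, 1.0, 50
        ab = paper_schedule.alpha_bar

        # independent scalar recursion (plain floats, no package code)
        x_scalar = np.sqrt(ab[lam - 1]) * c + np.sqrt(1 - ab[lam - 1]) * e
        for t in range(lam, 0, -1):
            abar, beta = ab[t - 1], paper_schedule.beta[t - 1]
            alpha = 1.0 - beta
            eps_hat = (x_scalar - np.sqrt(abar) * c) / np.sqrt(1 - abar)
            x_scalar = (x_scalar - beta / np.sqrt(1 - abar) * eps_hat) / np.sqrt(alpha)

        oracle = FunctionHandle(
            lambda x, t: (x - np.sqrt(ab[t - 1]) * c) / np.sqrt(1 - ab[t - 1]))
        x_lam = np.full((8, 8), np.sqrt(ab[lam - 1]) * c + np.sqrt(1 - ab[lam - 1]) * e)
        out = iterative_sample(x_lam, lam, oracle, paper_schedule,
                               deterministic=True, clip=None)
        np.testing.assert_allclose(out, x_scalar, atol=1e-10)
        assert np.abs(out - c).max() < 0.05
        assert oracle.eval_counter == lam

    def test_stochastic_chain_reproducible_under_seed(self, paper_schedule):
        handle = FunctionHandle(lambda x, t: np.zeros_like(x))
        x = np.full((8, 8), 0.2)
        a = iterative_sample(x, 20, handle, paper_schedule,
                             rng=np.random.default_rng(3))
        b = iterative_sample(x, 20, handle, paper_schedule,
                             rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


def test_forward_variance_stays_bounded(paper_schedule, rng):
    """Variance preservation: standardized x0 and eps keep Var(x_t) in [0.5, 1.5]."""
    x0 = rng.standard_normal((64, 64))
    x0 = (x0 - x0.mean()) / x0.std()
    eps = rng.standard_normal((64, 64))
    eps = (eps - eps.mean()) / eps.std()
    for t in (1, 100, 300, 500, 700, 1000):
        x_t = forward_diffuse(x0, eps, t, paper_schedule).x_t
        assert 0.5 <= x_t.var() <= 1.5
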