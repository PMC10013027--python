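"""Unit tests for the duplex-model right-hand side and its symmetries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaplex import (
    DimensionError,
    DuplexState,
    ModelParams,
    NumericalStateError,
    adaptation_fixed_point,
    rhs,
)

from conftest import random_small_state, small_params


def rhs_reference(state, params):
    """Naive scalar double-loop evaluation of the equations of motion.

    Written independently of the production kernel (plain Python, ordered
    sums, explicit trig), to act as an oracle.
    """
    n = params.n
    dphi1 = np.zeros(n)
    dphi2 = np.zeros(n)
    dk1 = np.zeros((n, n))
    dk2 = np.zeros((n, n))
    for i in range(n):
        acc1 = 0.0
        acc2 = 0.0
        for j in range(n):
            if j == i:
                continue
            acc1 += (params.adjacency[i, j] + state.kappa1[i, j]) * math.sin(
                state.phi1[i] - state.phi1[j] + params.alpha
            )
            acc2 += state.kappa2[i, j] * math.sin(
                state.phi2[i] - state.phi2[j] + params.alpha
            )
            dk1[i, j] = -params.eps1 * (
                state.kappa1[i, j] + math.sin(state.phi1[i] - state.phi1[j] - params.beta)
            )
            dk2[i, j] = -params.eps2 * (
                state.kappa2[i, j] + math.sin(state.phi2[i] - state.phi2[j] - params.beta)
            )
        dphi1[i] = (
            params.omega1[i]
            - acc1 / n
            - params.sigma * math.sin(state.phi1[i] - state.phi2[i])
        )
        dphi2[i] = (
            params.omega2
            - acc2 / n
            - params.sigma * math.sin(state.phi2[i] - state.phi1[i])
        )
    return dphi1, dphi2, dk1, dk2


class TestRhs:
    def test_identical_phases_zero_lags_gives_natural_frequencies(self):
        n = 5
        params = small_params(n=n, alpha=0.0, beta=0.0, sigma=0.3,
                              omega1=np.arange(n, dtype=float))
        zeros = np.zeros((n, n))
        state = DuplexState(np.full(n, 1.3), np.full(n, 1.3), zeros.copy(), zeros.copy())
        d = rhs(state, params)
        np.testing.assert_allclose(d.phi1, params.omega1, atol=1e-15)
        np.testing.assert_allclose(d.phi2, np.full(n, params.omega2), atol=1e-15)
        np.testing.assert_array_equal(d.kappa1, zeros)
        np.testing.assert_array_equal(d.kappa2, zeros)

    def test_layers_decouple_at_sigma_zero(self):
        params = small_params(n=4, sigma=0.0)
        state = random_small_state(n=4, seed=2)
        d_before = rhs(state, params)
        perturbed = state.copy()
        perturbed.phi1 += 0.731
        perturbed.kappa1 *= -0.5
        d_after = rhs(perturbed, params)
        np.testing.assert_array_equal(d_before.phi2, d_after.phi2)
        np.testing.assert_array_equal(d_before.kappa2, d_after.kappa2)

    def test_n2_term_by_term_oracle(self):
        """Hand-evaluated scalar expansion of the equations for n = 2."""
        alpha, beta, sigma = -0.28 * np.pi, 0.6 * np.pi, 0.3
        eps1, eps2 = 0.03, 0.3
        omega1 = np.array([0.0, 1.0])
        omega2 = 0.25
        params = ModelParams(n=2, omega1=omega1, omega2=omega2, alpha=alpha,
                             beta=beta, eps1=eps1, eps2=eps2, sigma=sigma,
                             adjacency=np.array([[0.0, 1.0], [1.0, 0.0]]))
        phi1 = np.array([0.0, np.pi / 2])
        phi2 = np.array([0.0, 0.0])
        k1 = np.array([[0.0, 0.4], [-0.7, 0.0]])
        k2 = np.array([[0.0, -0.2], [0.9, 0.0]])
        state = DuplexState(phi1, phi2, k1, k2)
        d = rhs(state, params)

        s = math.sin
        exp_dphi1_0 = 0.0 - 0.5 * (1 + 0.4) * s(0 - np.pi / 2 + alpha) - sigma * s(0 - 0)
        exp_dphi1_1 = 1.0 - 0.5 * (1 - 0.7) * s(np.pi / 2 - 0 + alpha) - sigma * s(np.pi / 2 - 0)
        exp_dphi2_0 = omega2 - 0.5 * (-0.2) * s(0 - 0 + alpha) - sigma * s(0 - 0)
        exp_dphi2_1 = omega2 - 0.5 * 0.9 * s(0 - 0 + alpha) - sigma * s(0 - np.pi / 2)
        np.testing.assert_allclose(d.phi1, [exp_dphi1_0, exp_dphi1_1], atol=1e-14)
        np.testing.assert_allclose(d.phi2, [exp_dphi2_0, exp_dphi2_1], atol=1e-14)
        np.testing.assert_allclose(
            d.kappa1[0, 1], -eps1 * (0.4 + s(0 - np.pi / 2 - beta)), atol=1e-14
        )
        np.testing.assert_allclose(
            d.kappa1[1, 0], -eps1 * (-0.7 + s(np.pi / 2 - 0 - beta)), atol=1e-14
        )
        np.testing.assert_allclose(
            d.kappa2[0, 1], -eps2 * (-0.2 + s(0 - 0 - beta)), atol=1e-14
        )
        np.testing.assert_allclose(
            d.kappa2[1, 0], -eps2 * (0.9 + s(0 - 0 - beta)), atol=1e-14
        )

    @pytest.mark.parametrize("n", [2, 3, 4])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_double_loop_oracle(self, n, seed):
        params = small_params(n=n, beta=0.55 * np.pi, omega1=np.linspace(0, 1, n))
        state = random_small_state(n=n, seed=seed)
        d = rhs(state, params)
        e_phi1, e_phi2, e_k1, e_k2 = rhs_reference(state, params)
        np.testing.assert_allclose(d.phi1, e_phi1, atol=1e-12)
        np.testing.assert_allclose(d.phi2, e_phi2, atol=1e-12)
        np.testing.assert_allclose(d.kappa1, e_k1, atol=1e-12)
        np.testing.assert_allclose(d.kappa2, e_k2, atol=1e-12)

    def test_kappa_derivative_diagonal_is_zero(self, params4, state4):
        d = rhs(state4, params4)
        assert np.all(np.diag(d.kappa1) == 0.0)
        assert np.all(np.diag(d.kappa2) == 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shift=st.floats(-10, 10), seed=st.integers(0, 50))
    def test_global_phase_shift_symmetry(self, shift, seed):
        params = small_params(n=4)
        state = random_small_state(n=4, seed=seed)
        shifted = state.copy()
        shifted.phi1 += shift
        shifted.phi2 += shift
        d0 = rhs(state, params)
        d1 = rhs(shifted, params)
        np.testing.assert_allclose(d0.phi1, d1.phi1, atol=1e-12)
        np.testing.assert_allclose(d0.phi2, d1.phi2, atol=1e-12)
        np.testing.assert_allclose(d0.kappa1, d1.kappa1, atol=1e-13)
        np.testing.assert_allclose(d0.kappa2, d1.kappa2, atol=1e-13)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 50))
    def test_permutation_equivariance(self, seed):
        n = 5
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        params = small_params(n=n, omega1=rng.normal(size=n))
        state = random_small_state(n=n, seed=seed + 100)
        d = rhs(state, params)
        p_params = small_params(n=n, omega1=params.omega1[perm])
        p_state = DuplexState(
            state.phi1[perm], state.phi2[perm],
            state.kappa1[np.ix_(perm, perm)], state.kappa2[np.ix_(perm, perm)],
        )
        d_p = rhs(p_state, p_params)
        np.testing.assert_allclose(d_p.phi1, d.phi1[perm], atol=1e-12)
        np.testing.assert_allclose(d_p.phi2, d.phi2[perm], atol=1e-12)
        np.testing.assert_allclose(d_p.kappa1, d.kappa1[np.ix_(perm, perm)], atol=1e-13)
        np.testing.assert_allclose(d_p.kappa2, d.kappa2[np.ix_(perm, perm)], atol=1e-13)

    def test_dimension_mismatch_raises(self, state4):
        params5 = small_params(n=5)
        with pytest.raises(DimensionError):
            rhs(state4, params5)

    def test_non_finite_state_raises(self, params4, state4):
        state4.phi1[0] = np.nan
        with pytest.raises(NumericalStateError):
            rhs(state4, params4)

    def test_literal_adaptation_switch(self, state4):
        params = small_params(n=4, literal_adaptation=True)
        bracketed = small_params(n=4)
        d_lit = rhs(state4, params)
        d_brk = rhs(state4, bracketed)
        i, j = 0, 1
        dphi = state4.phi1[i] - state4.phi1[j]
        expected = -params.eps1 * state4.kappa1[i, j] + math.sin(dphi - params.beta)
        assert d_lit.kappa1[i, j] == pytest.approx(expected, abs=1e-14)
        assert d_lit.kappa1[i, j] != pytest.approx(d_brk.kappa1[i, j], abs=1e-6)


class TestAdaptationFixedPoint:
    def test_zero_at_delta_equal_beta(self):
        assert adaptation_fixed_point(0.6 * np.pi, 0.6 * np.pi) == pytest.approx(0.0)

    def test_unit_at_symmetric_rule(self):
        assert adaptation_fixed_point(0.0, np.pi / 2) == pytest.approx(1.0)

    def test_scalar_value(self):
        expected = -math.sin(0.3 - 0.45 * math.pi)
        assert adaptation_fixed_point(0.3, 0.45 * np.pi) == pytest.approx(expected, abs=1e-15)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(delta=st.floats(-7, 7), beta=st.floats(-3.2, 3.2))
    def test_always_within_unit_bound(self, delta, beta):
        assert abs(adaptation_fixed_point(delta, beta)) <= 1.0


class TestValidation:
    def test_adjacency_must_be_binary_with_zero_diagonal(self):
        with pytest.raises(ValueError):
            small_params(n=3, adjacency=np.full((3, 3), 0.5))
        adj = np.ones((3, 3))
        with pytest.raises(ValueError):
            small_params(n=3, adjacency=adj)

    def test_timescale_ordering_warns_but_does_not_fail(self):
        with pytest.warns(UserWarning):
            small_params(n=3, eps1=0.5, eps2=0.1)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            small_params(n=3, sigma=-0.1)

    def test_state_diagonal_must_be_zero(self):
        k = np.eye(3)
        with pytest.raises(ValueError):
            DuplexState(np.zeros(3), np.zeros(3), k, np.zeros((3, 3)))
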