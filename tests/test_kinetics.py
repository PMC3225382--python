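"""Closed-form solution of the three-state scheme vs the independent ODE
oracle, and the exact apparent<->intrinsic parameter mappings."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bondkin import (
    ApparentParams,
    DegenerateRatesError,
    InfeasibleParametersError,
    IntrinsicRates,
    InvalidRateError,
    apparent_from_intrinsic,
    apparent_rates,
    intrinsic_from_apparent,
    ode_reference,
    rate_matrix,
    solution_coefficients,
    splitting_probabilities,
    state_probabilities,
    state_trajectories,
    survival,
)
from conftest import draw_feasible_rates


class TestRateMatrix:
    def test_structure_matches_scheme(self, example_rates):
        A = rate_matrix(example_rates)
        assert np.allclose(np.diag(A), [-5.0, -2.0, -0.5])
        assert A[1, 0] == 2.0 and A[2, 1] == 1.0
        assert A[0, 1] == A[0, 2] == A[1, 2] == A[2, 0] == 0.0
        # column sums are the negative dissociation rates (probability flux
        # out of the bound system)
        assert np.allclose(A.sum(axis=0), [-3.0, -1.0, -0.5])

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidRateError):
            IntrinsicRates(-1.0, 1.0, 1.0, 1.0, 1.0)

    def test_no_rupture_pathway_rejected(self):
        # all rates zero (and any scheme whose absorbing path is cut off)
        # describes a bond that never ruptures
        with pytest.raises(InvalidRateError):
            IntrinsicRates(0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(InvalidRateError):
            IntrinsicRates(1.0, 0.0, 0.0, 0.0, 0.5)

    def test_matrix_exponential_matches_ode(self, rng):
        from scipy.linalg import expm

        for _ in range(5):
            r = draw_feasible_rates(rng)
            t_grid = np.linspace(0.0, 20.0, 40)
            ode = ode_reference(r, t_grid)
            A = rate_matrix(r)
            for j, t in enumerate(t_grid):
                p = expm(A * t) @ np.array([1.0, 0.0, 0.0])
                assert np.abs(p - ode[:, j]).max() <= 1e-8


class TestApparentRates:
    def test_decoupled_states(self):
        assert apparent_rates(IntrinsicRates(0, 0, 3, 1, 0.5)) == (3, 1, 0.5)

    def test_triangular_diagonal(self, example_rates):
        assert apparent_rates(example_rates) == (5.0, 2.0, 0.5)

    def test_matches_eigendecomposition(self, rng):
        for _ in range(20):
            r = draw_feasible_rates(rng)
            eig = np.sort(-np.linalg.eigvals(rate_matrix(r)).real)[::-1]
            assert np.abs(np.array(apparent_rates(r)) - eig).max() <= 1e-10


class TestSolutionCoefficients:
    def test_pure_c1_decay(self):
        c = solution_coefficients(IntrinsicRates(0, 0, 3, 1, 0.5))
        assert c.a == (1.0, 0.0, 0.0)
        assert c.b == (0.0, 0.0, 0.0) and c.c == (0.0, 0.0, 0.0)

    def test_initial_condition_exact(self, rng):
        for _ in range(20):
            c = solution_coefficients(draw_feasible_rates(rng))
            assert sum(c.a) == 1.0
            assert sum(c.b) == 0.0  # p2(0) = 0 exactly
            assert abs(sum(c.c)) <= 1e-12  # p3(0) = 0

    def test_mode_weights_of_example(self, example_rates):
        w = solution_coefficients(example_rates).mode_weights
        assert np.allclose(w, [13 / 27, 6 / 27, 8 / 27], atol=1e-12)

    def test_degenerate_rates_raise(self):
        # k12 + kr1 == k23 + kr2 exactly
        with pytest.raises(DegenerateRatesError):
            solution_coefficients(IntrinsicRates(1.0, 1.0, 1.0, 1.0, 0.5))


class TestStateProbabilities:
    def test_initial_condition(self, example_rates):
        p = state_probabilities(example_rates, 0.0)
        assert (p.p1, p.p2, p.p3) == (1.0, 0.0, 0.0)

    def test_single_exponential_limit(self):
        p = state_probabilities(IntrinsicRates(0, 0, 2.0, 1.0, 0.5), 1.0)
        assert p.p1 == pytest.approx(np.exp(-2.0), abs=1e-14)
        assert p.p2 == 0.0 and p.p3 == 0.0

    def test_negative_time_rejected(self, example_rates):
        with pytest.raises(ValueError):
            state_probabilities(example_rates, -0.1)

    def test_closed_form_matches_ode_oracle(self, rng):
        t_grid = np.linspace(0.0, 50.0, 101)
        for _ in range(25):
            r = draw_feasible_rates(rng)
            closed = state_trajectories(r, t_grid)
            assert np.abs(closed - ode_reference(r, t_grid)).max() <= 1e-8

    def test_example_instance_at_t1(self, example_rates):
        p = state_probabilities(example_rates, 1.0)
        ode = ode_reference(example_rates, np.array([0.0, 1.0]))[:, 1]
        assert np.abs(np.array([p.p1, p.p2, p.p3]) - ode).max() <= 1e-8

    def test_continuity_across_degeneracy_tolerance(self):
        # two eigen-rates separated by just above vs just below the
        # degeneracy tolerance: trajectories must agree at the switch
        t = np.linspace(0.0, 20.0, 200)
        K2 = 2.0
        for gap_rel in (3e-9, 3e-10):  # above / below DEGENERACY_RTOL
            k1tot = K2 * (1 + gap_rel)
            r = IntrinsicRates(1.0, 1.5, k1tot - 1.0, 0.5, 0.1)
            p_closed = state_trajectories(r, t)
            p_ode = ode_reference(r, t)
            assert np.abs(p_closed - p_ode).max() <= 1e-6


class TestSurvival:
    def test_normalization_at_zero(self):
        p = ApparentParams(5, 2, 0.5, 13 / 27, 6 / 27, 8 / 27)
        assert survival(p, 0.0) == pytest.approx(1.0, abs=1e-15)

    def test_single_mode(self):
        p = ApparentParams(2.0, 1.0, 0.5, 1.0, 0.0, 0.0)
        assert survival(p, 1.0) == pytest.approx(np.exp(-2.0), abs=1e-15)

    def test_equals_summed_occupancies(self, example_rates):
        p = apparent_from_intrinsic(example_rates)
        t = np.linspace(0.0, 20.0, 100)
        total = state_trajectories(example_rates, t).sum(axis=0)
        assert np.abs(survival(p, t) - total).max() <= 1e-10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_survival_monotone_nonincreasing(self, seed):
        r = draw_feasible_rates(np.random.default_rng(seed))
        t = np.linspace(0.0, 50.0, 400)
        s = state_trajectories(r, t).sum(axis=0)
        assert s[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(s) <= 1e-12)
        assert s[-1] < s[0]


class TestParameterMappings:
    def test_decoupled_forward(self):
        p = apparent_from_intrinsic(IntrinsicRates(0, 0, 3, 1, 0.5))
        assert (p.k1, p.k2, p.k3) == (3.0, 1.0, 0.5)
        assert (p.w1, p.w2, p.w3) == (1.0, 0.0, 0.0)

    def test_example_weights(self, example_rates):
        p = apparent_from_intrinsic(example_rates)
        assert np.allclose(p.weights, [13 / 27, 6 / 27, 8 / 27], atol=1e-12)

    def test_weights_conserve_probability(self, rng):
        for _ in range(1000):
            p = apparent_from_intrinsic(draw_feasible_rates(rng))
            assert abs(p.weights.sum() - 1.0) <= 1e-12

    def test_decoupled_inverse(self):
        p = ApparentParams(3, 1, 0.5, 1.0, 0.0, 0.0)
        r = intrinsic_from_apparent(p)
        assert r.as_tuple() == (0.0, 0.0, 3.0, 1.0, 0.5)

    def test_fixed_instance_inverse(self):
        p = ApparentParams(5, 2, 0.5, 13 / 27, 6 / 27, 8 / 27)
        r = intrinsic_from_apparent(p)
        assert np.allclose(r.as_tuple(), (2, 1, 3, 1, 0.5), rtol=1e-10)

    def test_round_trip_bijection(self, rng):
        for _ in range(1000):
            r = draw_feasible_rates(rng)
            p = apparent_from_intrinsic(r)
            back = intrinsic_from_apparent(p)
            assert p.k3 == r.kr3  # kr3 = k3 identically
            rel = np.abs(np.array(back.as_tuple()) - np.array(r.as_tuple()))
            rel /= np.maximum(np.array(r.as_tuple()), 1e-30)
            assert rel.max() <= 1e-8

    def test_improper_mixture_rejected_at_type_boundary(self):
        # a proper sorted mixture always inverts to nonnegative rates
        # (kr1 = sum w_i k_i > 0, etc.), so infeasibility enters only via
        # out-of-range weights, which the type rejects with the quantity
        with pytest.raises(InfeasibleParametersError) as exc:
            ApparentParams(5.0, 2.0, 0.5, 1.2, -0.2, 0.0)
        assert exc.value.quantity is not None

    def test_project_mode_agrees_on_feasible_input(self, rng):
        for _ in range(20):
            p = apparent_from_intrinsic(draw_feasible_rates(rng))
            assert intrinsic_from_apparent(p, project=True) == \
                intrinsic_from_apparent(p)

    def test_degenerate_forward_raises(self):
        with pytest.raises(DegenerateRatesError):
            apparent_from_intrinsic(IntrinsicRates(1.0, 1.0, 1.0, 1.0, 0.5))

    def test_k12_to_zero_limit_is_pure_exponential(self):
        t = np.linspace(0.0, 10.0, 50)
        r = IntrinsicRates(1e-10, 1.0, 2.0, 0.7, 0.1)
        s = state_trajectories(r, t).sum(axis=0)
        assert np.abs(s - np.exp(-2.0 * t)).max() <= 1e-9


class TestSplittingProbabilities:
    def test_first_step_analysis(self, example_rates):
        # P(exit C1) = 3/5; P(exit C2) = 2/5 * 1/2; P(exit C3) = rest
        assert np.allclose(splitting_probabilities(example_rates),
                           [0.6, 0.2, 0.2])

    def test_sums_to_one(self, rng):
        for _ in range(50):
            assert splitting_probabilities(
                draw_feasible_rates(rng)).sum() == pytest.approx(1.0)


class TestOdeReference:
    def test_pure_decay(self):
        t = np.linspace(0.0, 5.0, 20)
        y = ode_reference(IntrinsicRates(0, 0, 2.0, 0.1, 0.1), t)
        assert np.abs(y[0] - np.exp(-2 * t)).max() <= 1e-8
        assert np.abs(y[1:]).max() <= 1e-10

    def test_unsorted_grid_rejected(self, example_rates):
        with pytest.raises(ValueError):
            ode_reference(example_rates, [1.0, 0.5, 2.0])
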