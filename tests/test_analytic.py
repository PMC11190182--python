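import math

import numpy as np
import pytest

import fptcme as f


class TestBirthDeathClosedForm:
    def test_single_event_from_zero(self):
        assert f.mfpt_birth_death_closed_form(1.0, 1, 0) == pytest.approx(1.0)

    def test_three_state_value(self):
        # equals (1/2)(2 + (2*1/2)(1/2)) and the first-step-analysis oracle
        assert f.mfpt_birth_death_closed_form(2.0, 2, 0) == pytest.approx(1.25)

    def test_start_at_target_is_zero(self):
        assert f.mfpt_birth_death_closed_form(5.0, 7, 7) == 0.0

    def test_start_above_target_rejected(self):
        with pytest.raises(ValueError):
            f.mfpt_birth_death_closed_form(5.0, 3, 4)

    def test_large_N_stays_finite_and_positive(self):
        # term recursion must not overflow or lose positivity at N ~ 900
        val = f.mfpt_birth_death_closed_form(1000.0, 800, 0)
        assert 0 < val < 10.0

    def test_additivity_in_initial_state(self):
        # tau(0 -> N) = tau(0 -> n) + tau(n -> N) for a skip-free chain
        K, N, n = 8.0, 12, 5
        total = f.mfpt_birth_death_closed_form(K, N, 0)
        legs = f.mfpt_birth_death_closed_form(
            K, n, 0
        ) + f.mfpt_birth_death_closed_form(K, N, n)
        assert total == pytest.approx(legs, rel=1e-12)


class TestDeterministicClosedForm:
    def test_values(self):
        assert f.deterministic_fpt_closed_form(0.8) == pytest.approx(
            1.6094379, abs=1e-6
        )
        assert f.deterministic_fpt_closed_form(0.9) == pytest.approx(
            2.3025851, abs=1e-6
        )

    def test_vanishes_for_small_fraction(self):
        assert f.deterministic_fpt_closed_form(1e-12) == pytest.approx(
            1e-12, rel=1e-3
        )

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.5, 1.5])
    def test_domain(self, rho):
        with pytest.raises(ValueError):
            f.deterministic_fpt_closed_form(rho)


class TestTaylorBound:
    def test_first_term(self):
        assert f.taylor_partial_sum(0.5, 1) == pytest.approx(0.5)

    def test_converges_to_log(self):
        assert f.taylor_partial_sum(0.5, 200) == pytest.approx(
            math.log(2.0), rel=1e-12
        )

    @pytest.mark.parametrize("rho", [0.1, 0.5, 0.9])
    @pytest.mark.parametrize("N", [1, 5, 40])
    def test_strictly_below_deterministic_time_and_increasing(self, rho, N):
        partial = f.taylor_partial_sum(rho, N)
        tau_d = f.deterministic_fpt_closed_form(rho)
        assert partial <= tau_d
        # strictness is only representable while the Taylor tail exceeds
        # double-precision resolution of tau_d
        tail = rho ** (N + 1) / (N + 1)
        if tail > 1e-15 * tau_d:
            assert partial < tau_d
            assert f.taylor_partial_sum(rho, N + 1) > partial


class TestBurstBoundary:
    def test_printed_value(self):
        assert f.bursty_regime_boundary(20.0, 10) == pytest.approx(
            200.0 * (1 - math.exp(-1 / 20.0)), rel=1e-12
        )
        assert f.bursty_regime_boundary(20.0, 10) == pytest.approx(9.754, abs=1e-3)

    def test_large_K_limit_is_burst_size(self):
        assert f.bursty_regime_boundary(1e8, 10) == pytest.approx(10.0, rel=1e-6)

    def test_simple_birth_death_excluded(self):
        # boundary < 1 for r = 1: no integer target can satisfy it
        for K in (0.5, 2.0, 50.0, 1e6):
            assert f.bursty_regime_boundary(K, 1) < 1.0

    def test_boundary_flips_the_comparison(self):
        # just below the boundary the deterministic route is faster than
        # the stochastic first-event time 1/K, just above it is slower
        K, r = 20.0, 10
        boundary = f.bursty_regime_boundary(K, r)
        system = f.bursty_bd(K=K, r=r).rre()
        below = f.deterministic_fpt(system, "P", boundary * 0.98).tau_d
        above = f.deterministic_fpt(system, "P", boundary * 1.02).tau_d
        assert below < 1.0 / K < above


class TestSteadyStateMeans:
    def test_printed_means(self):
        assert f.steady_state_mean("simple_bd", K=50) == 50.0
        assert f.steady_state_mean("bursty_bd", K=20, r=10) == 200.0
        assert f.steady_state_mean(
            "telegraph", lambda_on=2.0, mu_off=0.5, K=625.0
        ) == pytest.approx(500.0)
        assert f.steady_state_mean("bursty_geometric", K=20, b=10) == 200.0

    def test_feedback_has_no_closed_form(self):
        with pytest.raises(ValueError, match="feedback"):
            f.steady_state_mean("feedback", rho_u=1, rho_b=2)


class TestTargetFromFraction:
    @pytest.mark.parametrize(
        "mean,rho,expected", [(50, 0.8, 40), (500, 0.6, 300), (200, 0.2, 40)]
    )
    def test_printed_targets(self, mean, rho, expected):
        assert f.target_from_fraction(mean, rho) == expected

    def test_non_integer_floor(self):
        assert f.target_from_fraction(10.5, 0.5) == 5

    def test_trivial_target_rejected(self):
        with pytest.raises(ValueError):
            f.target_from_fraction(3.0, 0.1)


class TestNoiseSpeedsUpConstitutiveExpression:
    @pytest.mark.parametrize("rho", [round(0.1 * i, 1) for i in range(1, 10)])
    def test_stochastic_mean_below_deterministic_time(self, rho):
        for K in (2.0, 5.0, 20.0, 100.0):
            N = math.floor(rho * K)
            if N < 1:
                continue
            mfpt = f.mfpt_birth_death_closed_form(K, N, 0)
            assert mfpt < f.deterministic_fpt_closed_form(rho)

    def test_ratio_approaches_one_for_large_mean(self):
        rho = 0.8
        eta = f.mfpt_birth_death_closed_form(
            1000.0, 800, 0
        ) / f.deterministic_fpt_closed_form(rho)
        assert eta < 1.0
        assert abs(eta - 1.0) < 0.05

    def test_below_burst_target_waits_one_event(self):
        # bursty model with target under the burst size: MFPT = 1/K exactly
        bundle = f.bursty_bd(K=20.0, r=10)
        space = f.enumerate_states(bundle.network)
        A = f.build_transition_matrix(bundle.network, space)
        for N in (1, 5, 9):
            m = f.fpt_moments(A, space, f.TargetSet.threshold(0, N), k_max=1)
            assert m.mean_from([0]) == pytest.approx(1.0 / 20.0, rel=1e-10)
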