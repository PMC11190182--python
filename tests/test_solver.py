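import numpy as np
import pytest

import fptcme as f
from fptcme.solver import SingularReducedMatrixError, reduced_matrix


class TestReducedMatrix:
    def test_pure_birth_one_by_one(self, pure_birth):
        K, net, space, A = pure_birth
        y = f.TargetSet.threshold(0, 1).mask(space)
        A_Y_T, idx = reduced_matrix(A, y)
        np.testing.assert_allclose(A_Y_T.toarray(), [[-K]])
        assert idx.tolist() == [0]

    def test_birth_death_delete_top_state(self, tiny_bd):
        K, net = tiny_bd
        space = f.enumerate_states(net)
        A = f.build_transition_matrix(net, space)
        y = f.TargetSet.threshold(0, 2).mask(space)
        A_Y_T, idx = reduced_matrix(A, y)
        np.testing.assert_allclose(
            A_Y_T.toarray(), [[-K, K], [1.0, -(K + 1)]]
        )

    def test_empty_target_rejected(self, tiny_bd):
        K, net = tiny_bd
        space = f.enumerate_states(net)
        A = f.build_transition_matrix(net, space)
        with pytest.raises(ValueError, match="empty"):
            reduced_matrix(A, f.TargetSet.threshold(0, 99).mask(space))

    def test_all_absorbing_rejected(self, tiny_bd):
        K, net = tiny_bd
        space = f.enumerate_states(net)
        A = f.build_transition_matrix(net, space)
        with pytest.raises(ValueError, match="transient"):
            reduced_matrix(A, f.TargetSet.threshold(0, 0).mask(space))


class TestMoments:
    def test_pure_birth_exponential_moments(self, pure_birth):
        K, net, space, A = pure_birth
        m = f.fpt_moments(A, space, f.TargetSet.threshold(0, 1), k_max=2)
        assert m.mean_from([0]) == pytest.approx(1.0 / K, rel=1e-12)
        assert m.moment_from([0], 2) == pytest.approx(2.0 / K**2, rel=1e-12)

    def test_three_state_chain_first_step_values(self, bd2):
        # first-step analysis: T1 = 1/3 + T0/3, T0 = 1/2 + T1
        net, space, A = bd2
        m = f.fpt_moments(A, space, f.TargetSet.threshold(0, 2))
        assert m.mean_from([0]) == pytest.approx(1.25, rel=1e-10)
        assert m.mean_from([1]) == pytest.approx(0.75, rel=1e-10)

    def test_initial_state_inside_target_has_zero_moments(self, bd2):
        net, space, A = bd2
        m = f.fpt_moments(A, space, f.TargetSet.threshold(0, 2))
        assert m.mean_from([5]) == 0.0
        assert m.moment_from([7], 2) == 0.0

    def test_jensen_inequality_all_states(self):
        for bundle in (f.simple_bd(K=7.0), f.telegraph(1.0, 2.0, 30.0, rho=0.5)):
            space = f.enumerate_states(bundle.network)
            A = f.build_transition_matrix(bundle.network, space)
            target, _ = bundle.target(0.5)
            m = f.fpt_moments(A, space, target, k_max=2)
            assert np.all(m.raw_moments[1] >= m.raw_moments[0] ** 2 - 1e-9)

    def test_mean_non_increasing_in_initial_count(self):
        bundle = f.simple_bd(K=10.0)
        space = f.enumerate_states(bundle.network)
        A = f.build_transition_matrix(bundle.network, space)
        m = f.fpt_moments(A, space, f.TargetSet.threshold(0, 8))
        assert np.all(np.diff(m.mean) <= 1e-12)

    @pytest.mark.parametrize("K", [1.0, 2.0, 5.0, 10.0, 50.0])
    def test_matches_closed_form_across_initial_states(self, K):
        N = min(max(int(0.9 * K), 1), 20)
        bundle = f.simple_bd(K=K)
        space = f.enumerate_states(bundle.network)
        A = f.build_transition_matrix(bundle.network, space)
        m = f.fpt_moments(A, space, f.TargetSet.threshold(0, N))
        for n in range(N):
            expected = f.mfpt_birth_death_closed_form(K, N, n)
            assert m.mean_from([n]) == pytest.approx(expected, rel=1e-8)

    def test_unreachable_target_reports_dead_states(self):
        # death-only chain: from 0 the target {x >= 2} can never be reached
        net = f.ReactionNetwork(
            [f.SpeciesSpec("P", 0, 3)],
            [f.Reaction([1], [0], 1.0)],
        )
        space = f.enumerate_states(net)
        A = f.build_transition_matrix(net, space)
        with pytest.raises(SingularReducedMatrixError):
            f.fpt_moments(A, space, f.TargetSet.threshold(0, 2))


class TestRefinement:
    def test_converges_to_closed_form(self):
        bundle = f.simple_bd(K=50.0)
        m, report = f.mfpt_with_refinement(
            bundle.network, f.TargetSet.threshold("P", 40), rtol=1e-8
        )
        assert report.converged
        assert m.mean_from([0]) == pytest.approx(
            f.mfpt_birth_death_closed_form(50.0, 40, 0), rel=1e-8
        )

    def test_zero_rtol_rejected(self):
        bundle = f.simple_bd(K=5.0)
        with pytest.raises(ValueError, match="rtol"):
            f.mfpt_with_refinement(
                bundle.network, f.TargetSet.threshold("P", 4), rtol=0.0
            )

    def test_state_cap_reached_is_explicit(self):
        bundle = f.bursty_bd(K=20.0, r=10)
        # cap admits the initial truncation but forbids the first doubling
        with pytest.raises(RuntimeError, match="state cap"):
            f.mfpt_with_refinement(
                bundle.network,
                f.TargetSet.threshold("P", 180),
                rtol=1e-12,
                max_states=900,
            )

    def test_bursty_refined_mean_matches_ssa(self):
        bundle = f.bursty_bd(K=20.0, r=10)
        target, N = bundle.target(0.9)
        m, _ = f.mfpt_with_refinement(bundle.network, target)
        sample = f.ssa_fpt_sample(bundle.network, [0], target, 10_000, seed=11)
        z = abs(m.mean_from([0]) - sample.mean) / sample.standard_error
        assert z < 3.0


class TestMeanAndCV:
    def test_exponential_has_unit_cv2(self, pure_birth):
        K, net, space, A = pure_birth
        m = f.fpt_moments(A, space, f.TargetSet.threshold(0, 1), k_max=2)
        mean, cv2 = f.fpt_mean_and_cv(m)
        assert cv2[0] == pytest.approx(1.0, rel=1e-10)

    def test_inside_target_flagged_nan(self, bd2):
        net, space, A = bd2
        m = f.fpt_moments(A, space, f.TargetSet.threshold(0, 2))
        assert np.isnan(m.cv2_from([4]))

    def test_cv2_requires_second_moment(self, bd2):
        net, space, A = bd2
        m = f.fpt_moments(A, space, f.TargetSet.threshold(0, 2), k_max=1)
        with pytest.raises(ValueError):
            f.fpt_mean_and_cv(m)

    def test_cv2_agrees_with_ssa(self, bd2):
        net, space, A = bd2
        target = f.TargetSet.threshold(0, 2)
        m = f.fpt_moments(A, space, target, k_max=2)
        sample = f.ssa_fpt_sample(net, [0], target, 100_000, seed=17)
        # block jackknife for the sampling error of the empirical CV^2
        blocks = sample.samples.reshape(20, -1)
        cv2_blocks = blocks.var(axis=1, ddof=1) / blocks.mean(axis=1) ** 2
        se = cv2_blocks.std(ddof=1) / np.sqrt(len(cv2_blocks))
        cv2_ssa = sample.samples.var(ddof=1) / sample.mean**2
        assert abs(m.cv2_from([0]) - cv2_ssa) < 3 * se
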