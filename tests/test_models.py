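import numpy as np
import pytest

import fptcme as f
from tests_helpers import refined_mfpt


class TestBirthDeathFamily:
    def test_unit_burst_equals_simple_model(self):
        a = f.simple_bd(K=7.0)
        b = f.bursty_bd(K=7.0, r=1)
        sa = f.enumerate_states(a.network)
        sb = f.enumerate_states(b.network)
        Aa = f.build_transition_matrix(a.network, sa)
        Ab = f.build_transition_matrix(b.network, sb)
        assert (Aa != Ab).nnz == 0

    def test_burst_production_propensity_is_constant(self):
        b = f.bursty_bd(K=20.0, r=10)
        for state in ([0], [50], [199]):
            assert b.network.propensity(0, state) == 20.0

    def test_default_targets_match_printed_values(self):
        assert f.simple_bd(K=50.0).target(0.8)[1] == 40
        assert f.bursty_bd(K=20.0, r=10).target(0.9)[1] == 180
        assert f.bursty_bd(K=20.0, r=10).target(0.2)[1] == 40


class TestGeometricBursts:
    def test_unit_mean_degenerates_to_simple(self):
        b = f.bursty_bd_geometric(K=5.0, b=1.0)
        assert len(b.network.reactions) == 2
        assert b.network.reactions[0].product_stoich[0] == 1

    def test_burst_distribution_mean_is_b(self):
        b = f.bursty_bd_geometric(K=20.0, b=10.0)
        mean = float(np.dot(b.burst_sizes, b.burst_probs))
        assert abs(mean - 10.0) < 1e-10
        assert abs(b.burst_probs.sum() - 1.0) < 1e-12

    def test_total_burst_frequency_preserved(self):
        b = f.bursty_bd_geometric(K=20.0, b=10.0)
        total = sum(
            r.rate_constant
            for r in b.network.reactions
            if r.product_stoich[0] > 0
        )
        assert total == pytest.approx(20.0, rel=1e-12)

    def test_fsp_matches_ssa(self):
        b = f.bursty_bd_geometric(K=10.0, b=3.0, rho=0.8)
        target, _ = b.target()
        mfpt = refined_mfpt(b, target)
        s = f.ssa_fpt_sample(b.network, [0], target, 5000, seed=23)
        assert abs(mfpt - s.mean) < 3 * s.standard_error


class TestTelegraph:
    def test_state_space_is_two_gene_copies_of_mrna_range(self):
        b = f.telegraph()
        space = f.enumerate_states(b.network)
        bound = b.network.bounds[1]
        assert space.n_states == 2 * (bound + 1)

    def test_activation_only_fires_when_inactive(self):
        b = f.telegraph(lambda_on=2.0, mu_off=0.5, K=625.0)
        assert b.network.propensity(0, [0, 3]) == 2.0
        assert b.network.propensity(0, [1, 3]) == 0.0

    def test_mfpt_bounded_below_by_activation_time(self):
        b = f.telegraph(lambda_on=2.0, mu_off=0.5, K=50.0, rho=0.5)
        target = f.TargetSet.threshold("M", 1)
        mfpt = refined_mfpt(b, target)
        assert mfpt >= 1.0 / 2.0

    def test_fast_switching_limit_is_constitutive(self):
        lam, mu = 1000.0, 250.0
        mean = 40.0
        K = mean * (lam + mu) / lam
        tele = f.telegraph(lambda_on=lam, mu_off=mu, K=K, rho=0.5)
        simple = f.simple_bd(K=mean, rho=0.5)
        target_t, N = tele.target(0.5)
        target_s, _ = simple.target(0.5)
        mfpt_t = refined_mfpt(tele, target_t)
        mfpt_s = refined_mfpt(simple, target_s)
        assert mfpt_t == pytest.approx(mfpt_s, rel=0.02)


class TestFeedback:
    def test_binding_propensity_counts_free_protein(self):
        b = f.feedback(rho_u=10.0, rho_b=50.0, sigma_b=0.5, sigma_u=20.0)
        assert b.network.propensity(0, [1, 3]) == pytest.approx(3 * 0.5)
        assert b.network.propensity(0, [0, 3]) == 0.0

    def test_bound_production_only_when_bound(self):
        b = f.feedback(rho_u=10.0, rho_b=50.0, sigma_b=0.5, sigma_u=20.0)
        assert b.network.propensity(3, [0, 5]) == 50.0
        assert b.network.propensity(3, [1, 5]) == 0.0

    def test_binding_conserves_protein_plus_gene_occupancy(self):
        b = f.feedback()
        bind = b.network.reactions[0]
        unbind = b.network.reactions[1]
        state = np.array([1, 4])
        assert f.apply_reaction(state, bind).tolist() == [0, 3]
        assert f.apply_reaction(
            f.apply_reaction(state, bind), unbind
        ).tolist() == [1, 4]

    def test_weak_binding_limit_is_constitutive(self):
        fb = f.feedback(
            rho_u=12.0, rho_b=500.0, sigma_b=1e-6, sigma_u=20.0, rho=0.5
        )
        simple = f.simple_bd(K=12.0, rho=0.5)
        t_fb, _ = fb.target(0.5)
        t_s, _ = simple.target(0.5)
        mfpt_fb = refined_mfpt(fb, t_fb, initial_state=[1, 0])
        mfpt_s = refined_mfpt(simple, t_s)
        assert mfpt_fb == pytest.approx(mfpt_s, rel=0.01)

    def test_equal_rates_behave_constitutively(self):
        fb = f.feedback(rho_u=15.0, rho_b=15.0, sigma_b=0.5, sigma_u=5.0)
        res = f.eta(fb, 0.8)
        assert res.mfpt < res.tau_d


class TestBundleConsistency:
    @pytest.mark.parametrize(
        "bundle",
        [
            f.simple_bd(K=50.0),
            f.bursty_bd(K=20.0, r=10),
            f.bursty_bd_geometric(K=20.0, b=10.0),
            f.telegraph(),
        ],
        ids=["simple", "bursty", "geom", "telegraph"],
    )
    def test_rre_steady_state_matches_closed_form(self, bundle):
        ss = f.steady_state(bundle.rre())
        idx = bundle.network.species_index(bundle.threshold_species)
        assert ss[idx] == pytest.approx(bundle.steady_state_mean(), rel=1e-6)

    def test_registry_round_trip(self):
        b = f.make_model("telegraph", lambda_on=1.0, mu_off=1.0, K=30.0)
        assert b.name == "telegraph"
        with pytest.raises(KeyError):
            f.make_model("nope")
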