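"""Two-region diversification likelihood, scenarios, fitting, MCMC."""

import numpy as np
import pytest

import biomediv as bd
from biomediv.geosse import (GeoSSEModel, GeoSSEResults, RATE_NAMES,
                             SCENARIOS, ScenarioSpec)
from conftest import random_geosse_instance
from _oracles import geosse_loglik_rk4

CHERRY_RATES = bd.GeoSSEParams(sA=0.15, sB=0.04, sAB=0.0, xA=0.05, xB=0.2,
                               dA=0.1, dB=0.01)
# frozen value computed with the fine-step RK4 oracle (step 1e-3) before the
# production solver existed
CHERRY_LNL = -5.5116879022736835


class TestLoglik:
    def test_cherry_matches_oracle(self, cherry):
        ll = bd.geosse_loglik(cherry, {"A": 1, "B": 2}, CHERRY_RATES)
        assert ll == pytest.approx(CHERRY_LNL, abs=1e-6)
        oracle = geosse_loglik_rk4(cherry, {"A": 1, "B": 2},
                                   CHERRY_RATES.as_array(), step=1e-3)
        assert ll == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_rk4_oracle_on_random_instances(self, seed):
        tree, states, rates, rho = random_geosse_instance(seed)
        got = bd.geosse_loglik(tree, states, bd.GeoSSEParams(*rates), rho)
        want = geosse_loglik_rk4(tree, states, rates, sampling=rho, step=2e-3)
        assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_region_swap_symmetry(self, seed):
        tree, states, rates, rho = random_geosse_instance(seed + 30)
        params = bd.GeoSSEParams(*rates)
        ll = bd.geosse_loglik(tree, states, params, rho)
        swapped_states = {k: {1: 2, 2: 1, 0: 0}[v] for k, v in states.items()}
        swapped_rho = (rho[0], rho[2], rho[1])
        ll_swap = bd.geosse_loglik(tree, swapped_states,
                                   params.swap_regions(), swapped_rho)
        assert ll == pytest.approx(ll_swap, abs=1e-10)

    def test_complete_sampling_tip_conditions(self, cherry):
        m = GeoSSEModel(cherry, {"A": 1, "B": 2}, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(m._e_init, [0.0, 0.0, 0.0])
        tipA = cherry.tip_index()["A"]
        np.testing.assert_allclose(m._d_tips[tipA], [1.0, 0.0, 0.0])

    def test_child_order_invariance(self):
        a = bd.parse_newick("((A:1,B:1):1,C:2);")
        b = bd.parse_newick("(C:2,(B:1,A:1):1);")
        states = {"A": 1, "B": 2, "C": 0}
        la = bd.geosse_loglik(a, states, CHERRY_RATES)
        lb = bd.geosse_loglik(b, states, CHERRY_RATES)
        assert la == pytest.approx(lb, abs=1e-12)

    def test_missing_tip_state_error(self, cherry):
        with pytest.raises(ValueError, match="B"):
            bd.geosse_loglik(cherry, {"A": 1}, CHERRY_RATES)

    def test_non_ultrametric_rejected(self):
        t = bd.parse_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(Exception, match="ultrametric"):
            bd.geosse_loglik(t, {"A": 1, "B": 2, "C": 0}, CHERRY_RATES)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            bd.GeoSSEParams(-0.1, 0.1, 0, 0.1, 0.1, 0.1, 0.1)

    @pytest.mark.parametrize("mode", ["obs", "equal", "survival"])
    def test_root_modes_finite_and_distinct(self, cherry, mode):
        ll = GeoSSEModel(cherry, {"A": 1, "B": 2},
                         root=mode).loglik(CHERRY_RATES)
        assert np.isfinite(ll)


class TestTimeDependence:
    def test_zero_slopes_reduce_to_constant(self, three_tip):
        states = {"A": 1, "B": 2, "C": 0}
        lp = bd.GeoSSELinearParams(intercepts=CHERRY_RATES)
        assert bd.geosse_loglik_timedep(three_tip, states, lp) == pytest.approx(
            bd.geosse_loglik(three_tip, states, CHERRY_RATES), abs=1e-9)

    def test_negative_rate_clamped_likelihood_finite(self, three_tip):
        states = {"A": 1, "B": 2, "C": 0}
        lp = bd.GeoSSELinearParams(intercepts=CHERRY_RATES,
                                   slopes=(-0.2, 0, 0, 0, 0, 0, 0))
        ll = bd.geosse_loglik_timedep(three_tip, states, lp)
        assert np.isfinite(ll)

    def test_matches_oracle_with_slope(self):
        tree, states, rates, _ = random_geosse_instance(77, n_lo=3, n_hi=3,
                                                        random_rho=False)
        slopes = (0.02, 0, 0, 0.01, 0, 0, 0)
        lp = bd.GeoSSELinearParams(intercepts=bd.GeoSSEParams(*rates),
                                   slopes=slopes)
        got = bd.geosse_loglik_timedep(tree, states, lp)
        want = geosse_loglik_rk4(tree, states, rates, step=1e-3, slopes=slopes)
        assert got == pytest.approx(want, abs=1e-6)


class TestScenarios:
    def test_sixteen_distinct_scenarios(self):
        assert len(SCENARIOS) == 16
        combos = {(s.s_equal, s.x_equal, s.d_equal, s.sab_zero)
                  for s in SCENARIOS}
        assert len(combos) == 16  # the full 2^4 constraint lattice

    def test_scenario_11_is_triple_rate_equality(self):
        sc = SCENARIOS[10]
        assert sc.s_equal and sc.x_equal and sc.d_equal and not sc.sab_zero
        assert sc.k == 4

    def test_full_model_unconstrained(self):
        sc = SCENARIOS[0]
        assert sc.k == 7 and sc.label() == "full"

    def test_expand_applies_constraints_exactly(self):
        sc = ScenarioSpec(id=0, s_equal=True, sab_zero=True)
        p = sc.expand([0.3, 0.1, 0.2, 0.05, 0.07])
        assert p.sA == p.sB == 0.3
        assert p.sAB == 0.0
        assert p.xA == 0.1 and p.xB == 0.2

    def test_aic_arithmetic_prefers_parsimonious(self, cherry):
        m = GeoSSEModel(cherry, {"A": 1, "B": 2})
        full = GeoSSEResults(model=m, scenario=SCENARIOS[0],
                             params=CHERRY_RATES, loglik=-100.0, k=7)
        constrained = GeoSSEResults(model=m, scenario=SCENARIOS[10],
                                    params=CHERRY_RATES, loglik=-101.0, k=4)
        assert full.aic == pytest.approx(214.0)
        assert constrained.aic == pytest.approx(210.0)
        assert constrained.aic < full.aic


@pytest.fixture(scope="module")
def fitted():
    gen = bd.GeoSSEParams(0.2, 0.08, 0.0, 0.03, 0.1, 0.08, 0.02)
    tree, states = bd.sim_geosse_tree(bd.SimConfig(
        seed=11, n_taxa=80, geosse_params=gen, root_state=0))
    model = GeoSSEModel(tree, states)
    return model, model.fit(1, n_restarts=1, seed=0)


@pytest.fixture(scope="module")
def small_model():
    gen = bd.GeoSSEParams(0.25, 0.1, 0.0, 0.05, 0.05, 0.1, 0.05)
    tree, states = bd.sim_geosse_tree(bd.SimConfig(
        seed=31, n_taxa=40, geosse_params=gen, root_state=0))
    return GeoSSEModel(tree, states)


class TestFitting:
    def test_full_fit_k_and_aic(self, fitted):
        _, fit = fitted
        assert fit.k == 7
        assert fit.aic == pytest.approx(2 * 7 - 2 * fit.loglik)
        assert "GeoSSE" in fit.summary()

    def test_constrained_never_beats_full(self, fitted):
        model, full = fitted
        for sid in (2, 11, 16):
            sub = model.fit(sid, n_restarts=1, seed=1,
                            start=full.params)
            assert sub.loglik <= full.loglik + 1e-6
            assert sub.k == SCENARIOS[sid - 1].k

    def test_battery_has_16_rows_and_consistent_daic(self, fitted):
        model, _ = fitted
        bat = model.fit_battery(seed=0)
        tab = bat.table()
        assert len(tab) == 16
        assert tab.dAIC.min() == pytest.approx(0.0)
        assert bat.best.aic == tab.AIC.min()
        assert all(f.aic - bat.best.aic < 2 for f in bat.supported())

    def test_timedep_fit_reduces_and_reports_2k(self):
        gen = bd.GeoSSEParams(0.25, 0.1, 0.0, 0.03, 0.05, 0.08, 0.02)
        tree, states = bd.sim_geosse_tree(bd.SimConfig(
            seed=21, n_taxa=40, geosse_params=gen, root_state=0))
        model = GeoSSEModel(tree, states)
        fit = model.fit(11, timedep=True, n_restarts=0, seed=0)
        assert fit.k == 8  # 4 intercepts + 4 slopes
        assert isinstance(fit.params, bd.GeoSSELinearParams)
        assert np.isfinite(fit.loglik)


class TestMCMC:
    def test_same_seed_identical_chains(self, small_model):
        a = small_model.mcmc(11, n_steps=60, seed=5)
        b = small_model.mcmc(11, n_steps=60, seed=5)
        assert a.draws.equals(b.draws)
        assert a.acceptance_rate == b.acceptance_rate

    def test_different_seed_differs(self, small_model):
        a = small_model.mcmc(11, n_steps=60, seed=5)
        c = small_model.mcmc(11, n_steps=60, seed=6)
        assert not a.draws.equals(c.draws)

    def test_acceptance_rate_interior(self, small_model):
        s = small_model.mcmc(11, n_steps=150, seed=2)
        assert 0.0 < s.acceptance_rate < 1.0
        assert (s.draws > 0).all().all()
        assert set(s.draws.columns) == set(SCENARIOS[10].free_names)

    def test_summary_quantiles_ordered(self, small_model):
        s = small_model.mcmc(11, n_steps=100, seed=3).summary()
        assert (s["q2.5"] <= s["median"]).all()
        assert (s["median"] <= s["q97.5"]).all()

    def test_invalid_steps(self, small_model):
        with pytest.raises(ValueError):
            small_model.mcmc(11, n_steps=0, seed=1)
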