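"""Piecewise birth-death likelihood, shift fitting, LRT model selection."""

import numpy as np
import pytest

import biomediv as bd
from biomediv.bdshift import EpochModel, ShiftFit, select_shift_count
from _oracles import yule_loglik


def sim_tree(seed, n_taxa=50, lam=0.3, mu=0.1):
    em = EpochModel(lam=(lam,), mu=(mu,), rho=1.0)
    tree, _ = bd.sim_bd_tree(bd.SimConfig(seed=seed, n_taxa=n_taxa,
                                          epoch_model=em))
    return tree


class TestEpochModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            EpochModel(lam=(-0.1,), mu=(0.0,))
        with pytest.raises(ValueError):
            EpochModel(lam=(1, 1), mu=(0, 0), shift_ages=(1.0, 2.0))  # not decreasing
        with pytest.raises(ValueError):
            EpochModel(lam=(1,), mu=(0,), rho=0.0)
        with pytest.raises(ValueError):
            EpochModel(lam=(1, 1), mu=(0,), shift_ages=(1.0,))

    def test_derived_quantities(self):
        em = EpochModel(lam=(0.4, 0.2), mu=(0.1, 0.1), shift_ages=(5.0,))
        np.testing.assert_allclose(em.turnover(), [0.25, 0.5])
        np.testing.assert_allclose(em.net_diversification(), [0.3, 0.1])

    def test_epoch_lookup(self):
        em = EpochModel(lam=(0.4, 0.2), mu=(0.0, 0.0), shift_ages=(5.0,))
        lam_young, _ = em.rate_at(1.0)
        lam_old, _ = em.rate_at(9.0)
        assert lam_young[0] == 0.2 and lam_old[0] == 0.4


class TestLoglik:
    @pytest.mark.parametrize("seed", range(10))
    def test_pure_birth_matches_closed_form(self, seed):
        tree = sim_tree(seed, n_taxa=30, lam=0.4, mu=0.0)
        lam = np.random.default_rng(seed).uniform(0.1, 0.8)
        em = EpochModel(lam=(lam,), mu=(0.0,), rho=1.0)
        assert bd.bd_loglik(tree, em) == pytest.approx(
            yule_loglik(tree.branching_times(), lam), abs=1e-8)

    def test_degenerate_shift_equals_no_shift(self):
        tree = sim_tree(3)
        em0 = EpochModel(lam=(0.3,), mu=(0.1,), rho=0.7)
        h = tree.height
        em1 = EpochModel(lam=(0.3, 0.3), mu=(0.1, 0.1),
                         shift_ages=(h / 2,), rho=0.7)
        assert bd.bd_loglik(tree, em1) == pytest.approx(
            bd.bd_loglik(tree, em0), abs=1e-9)

    def test_equal_rates_analytic_limit(self):
        # lambda == mu must go through the logistic limit, not blow up
        tree = sim_tree(5)
        em = EpochModel(lam=(0.3,), mu=(0.3,), rho=0.9)
        assert np.isfinite(bd.bd_loglik(tree, em))

    def test_piecewise_structure_in_shift_age(self):
        # Between branching times the likelihood is continuous in the shift
        # age; crossing a node age it jumps by exactly ln(lam_old/lam_young),
        # the switch in the rate multiplying that branching event.
        tree = sim_tree(4, n_taxa=20)
        x = tree.branching_times()
        mid = 0.5 * (x[3] + x[4])  # strictly between two node ages

        def ll(age):
            em = EpochModel(lam=(0.4, 0.2), mu=(0.05, 0.05),
                            shift_ages=(age,), rho=1.0)
            return bd.bd_loglik(tree, em)

        assert ll(mid - 1e-6) == pytest.approx(ll(mid + 1e-6), abs=1e-4)
        # shift just above the node puts the event in the young epoch
        jump = ll(x[3] + 1e-9) - ll(x[3] - 1e-9)
        assert jump == pytest.approx(np.log(0.2 / 0.4), abs=1e-4)

    def test_tip_relabelling_invariance(self):
        tree = sim_tree(6, n_taxa=15)
        labels = list(tree.labels)
        tips = [i for i, l in enumerate(labels) if l is not None]
        perm = np.random.default_rng(0).permutation(len(tips))
        for i, j in zip(tips, perm):
            labels[i] = f"z{j}"
        shuffled = bd.Phylogeny(tree.parent, tree.length, labels)
        em = EpochModel(lam=(0.3, 0.2), mu=(0.1, 0.0),
                        shift_ages=(tree.height / 3,), rho=0.8)
        assert bd.bd_loglik(tree, em) == pytest.approx(
            bd.bd_loglik(shuffled, em), abs=1e-12)

    def test_shift_age_outside_tree_error(self):
        tree = sim_tree(7)
        em = EpochModel(lam=(0.3, 0.2), mu=(0, 0),
                        shift_ages=(tree.height * 2,))
        with pytest.raises(ValueError, match="shift age"):
            bd.bd_loglik(tree, em)

    def test_sampling_fraction_lowers_likelihood_of_dense_tree(self):
        tree = sim_tree(8, n_taxa=40, lam=0.4, mu=0.0)
        em_full = EpochModel(lam=(0.4,), mu=(0.0,), rho=1.0)
        em_sparse = EpochModel(lam=(0.4,), mu=(0.0,), rho=0.3)
        assert bd.bd_loglik(tree, em_full) != pytest.approx(
            bd.bd_loglik(tree, em_sparse))


class TestFit:
    def test_m_exceeding_internal_nodes_error(self, cherry):
        model = bd.BirthDeathShiftModel(cherry)
        with pytest.raises(ValueError, match="internal nodes"):
            model.fit(1)

    def test_yule_rates_recovered(self):
        # pure-birth truth: extinction pinned near zero, lambda near truth
        errs, mus = [], []
        for seed in range(20):
            tree = sim_tree(seed + 40, n_taxa=200, lam=0.3, mu=0.0)
            fit = bd.BirthDeathShiftModel(tree, rho=1.0).fit(0, seed=seed)
            errs.append(abs(fit.model.lam[0] - 0.3) / 0.3)
            mus.append(fit.model.mu[0])
        assert np.median(errs) < 0.25
        assert np.median(mus) <= 0.02

    def test_sequence_nesting_and_shift_recovery(self):
        em = EpochModel(lam=(0.1, 0.3), mu=(0.0, 0.0), shift_ages=(5.0,))
        tree, _ = bd.sim_bd_tree(bd.SimConfig(seed=2, span=33.0,
                                              epoch_model=em))
        model = bd.BirthDeathShiftModel(tree, rho=1.0)
        fits = model.fit_sequence(max_shifts=2, seed=0)
        lnls = [f.loglik for f in fits]
        assert lnls == sorted(lnls)  # non-decreasing in m
        assert fits[1].model.shift_ages[0] == pytest.approx(5.0, abs=2 * 33 / 100)
        assert fits[1].k == 5 and fits[0].k == 2 and fits[2].k == 8

    def test_fit_with_subsampled_tree_runs(self):
        em = EpochModel(lam=(0.4,), mu=(0.05,), rho=0.7)
        tree, _ = bd.sim_bd_tree(bd.SimConfig(seed=9, n_taxa=80,
                                              epoch_model=em, rho=0.7))
        fit = bd.BirthDeathShiftModel(tree, rho=0.7).fit(0, seed=0)
        assert np.isfinite(fit.loglik) and fit.aic == pytest.approx(
            2 * 2 - 2 * fit.loglik)


class TestSelect:
    def _fit(self, m, lnl):
        em = EpochModel(lam=(0.3,) * (m + 1), mu=(0.1,) * (m + 1),
                        shift_ages=tuple(10.0 - i for i in range(m)))
        return ShiftFit(model=em, loglik=lnl, m=m)

    def test_identical_likelihoods_select_zero(self):
        fits = [self._fit(m, -100.0) for m in range(4)]
        m, pvals = select_shift_count(fits)
        assert m == 0
        assert all(p == pytest.approx(1.0) for p in pvals)

    def test_large_improvement_accepts_shift(self):
        # 2 dlnL = 20 on 3 df: tail p ~= 1.70e-4 (independent closed form
        # 2(1-Phi(sqrt(x))) + sqrt(2x/pi) exp(-x/2) for df 3)
        fits = [self._fit(0, -110.0), self._fit(1, -100.0)]
        m, pvals = select_shift_count(fits, alpha=0.05)
        assert m == 1
        assert pvals[0] == pytest.approx(1.697e-4, rel=1e-3)

    def test_stops_at_first_failure(self):
        fits = [self._fit(0, -110.0), self._fit(1, -100.0),
                self._fit(2, -99.9), self._fit(3, -80.0)]
        m, _ = select_shift_count(fits)
        assert m == 1  # step 2->3 never reached after 1->2 fails

    def test_decreasing_likelihood_error(self):
        fits = [self._fit(0, -100.0), self._fit(1, -101.0)]
        with pytest.raises(ValueError, match="decreased"):
            select_shift_count(fits)

    def test_unordered_fits_error(self):
        fits = [self._fit(1, -100.0), self._fit(0, -110.0)]
        with pytest.raises(ValueError, match="ordered"):
            select_shift_count(fits)
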