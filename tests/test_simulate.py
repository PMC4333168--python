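"""Synthetic-data generators: determinism, closure, distributional checks."""

import numpy as np
import pytest
from scipy import stats

import biomediv as bd


class TestConfig:
    def test_exactly_one_stopping_rule(self):
        em = bd.EpochModel(lam=(0.3,), mu=(0.0,))
        with pytest.raises(ValueError):
            bd.SimConfig(seed=1, epoch_model=em)
        with pytest.raises(ValueError):
            bd.SimConfig(seed=1, n_taxa=10, span=5.0, epoch_model=em)

    def test_epoch_shifts_require_span_stopping(self):
        em = bd.EpochModel(lam=(0.1, 0.3), mu=(0, 0), shift_ages=(5.0,))
        with pytest.raises(ValueError, match="single-epoch"):
            bd.sim_bd_tree(bd.SimConfig(seed=1, n_taxa=50, epoch_model=em))


class TestBDTree:
    def test_seed_determinism_bytewise(self):
        em = bd.EpochModel(lam=(0.4,), mu=(0.1,))
        cfg = bd.SimConfig(seed=42, n_taxa=30, epoch_model=em)
        t1, _ = bd.sim_bd_tree(cfg)
        t2, _ = bd.sim_bd_tree(cfg)
        assert bd.write_newick(t1) == bd.write_newick(t2)

    def test_target_taxon_count_and_ultrametric(self):
        em = bd.EpochModel(lam=(0.4,), mu=(0.1,))
        tree, echo = bd.sim_bd_tree(bd.SimConfig(seed=3, n_taxa=25,
                                                 epoch_model=em))
        assert tree.n_tips == 25
        assert bd.validate_dated(tree)[0]
        assert echo.lam == (0.4,)

    def test_span_stopping_sets_crown_age(self):
        em = bd.EpochModel(lam=(0.5,), mu=(0.0,))
        tree, _ = bd.sim_bd_tree(bd.SimConfig(seed=5, span=4.0,
                                              epoch_model=em))
        assert tree.height == pytest.approx(4.0, abs=1e-9)

    def test_yule_mean_tip_count(self):
        # crown pure birth: E[N(T)] = 2 e^{lam T}; survival conditioning
        # inflates slightly, so allow generous Monte-Carlo slack
        em = bd.EpochModel(lam=(0.5,), mu=(0.0,))
        n = [bd.sim_bd_tree(bd.SimConfig(seed=s, span=4.0,
                                         epoch_model=em))[0].n_tips
             for s in range(150)]
        expected = 2 * np.exp(0.5 * 4.0)
        assert abs(np.mean(n) - expected) < 0.35 * expected

    def test_degenerate_epochs_match_constant_rate_distribution(self):
        em_const = bd.EpochModel(lam=(0.4,), mu=(0.05,))
        em_split = bd.EpochModel(lam=(0.4, 0.4), mu=(0.05, 0.05),
                                 shift_ages=(3.0,))
        n1 = [bd.sim_bd_tree(bd.SimConfig(seed=s, span=6.0,
                                          epoch_model=em_const))[0].n_tips
              for s in range(120)]
        n2 = [bd.sim_bd_tree(bd.SimConfig(seed=10_000 + s, span=6.0,
                                          epoch_model=em_split))[0].n_tips
              for s in range(120)]
        assert stats.ks_2samp(n1, n2).pvalue > 0.01

    def test_subsampling_reduces_tips(self):
        em = bd.EpochModel(lam=(0.5,), mu=(0.0,))
        full, _ = bd.sim_bd_tree(bd.SimConfig(seed=8, span=6.0, epoch_model=em))
        sub, _ = bd.sim_bd_tree(bd.SimConfig(seed=8, span=6.0, epoch_model=em,
                                             rho=0.5))
        assert sub.n_tips < full.n_tips


class TestGeoSSETree:
    def test_seed_determinism_bytewise(self):
        p = bd.GeoSSEParams(0.3, 0.2, 0.05, 0.1, 0.1, 0.1, 0.1)
        cfg = bd.SimConfig(seed=9, n_taxa=30, geosse_params=p)
        t1, s1 = bd.sim_geosse_tree(cfg)
        t2, s2 = bd.sim_geosse_tree(cfg)
        assert bd.write_newick(t1) == bd.write_newick(t2)
        assert s1 == s2

    def test_no_dispersal_closure(self):
        # no path out of region A: every tip stays tropical-endemic
        p = bd.GeoSSEParams(0.4, 0.4, 0.0, 0.05, 0.05, 0.0, 0.0)
        _, states = bd.sim_geosse_tree(bd.SimConfig(seed=2, n_taxa=40,
                                                    geosse_params=p,
                                                    root_state=1))
        assert set(states.values()) == {1}

    def test_symmetric_rates_balance_endemic_states(self):
        p = bd.GeoSSEParams(0.3, 0.3, 0.05, 0.05, 0.05, 0.1, 0.1)
        n1 = n2 = 0
        for s in range(100):
            _, states = bd.sim_geosse_tree(bd.SimConfig(
                seed=500 + s, n_taxa=20, geosse_params=p, root_state=0))
            vals = list(states.values())
            n1 += vals.count(1)
            n2 += vals.count(2)
        # binomial-scale fluctuation around equality
        assert abs(n1 - n2) < 4 * np.sqrt(n1 + n2)

    def test_per_state_subsampling(self):
        p = bd.GeoSSEParams(0.3, 0.3, 0.05, 0.02, 0.02, 0.1, 0.1)
        rho = bd.SamplingFractions(rho0=1.0, rho1=0.3, rho2=1.0)
        full, sf = bd.sim_geosse_tree(bd.SimConfig(seed=6, n_taxa=60,
                                                   geosse_params=p))
        sub, ss = bd.sim_geosse_tree(bd.SimConfig(seed=6, n_taxa=60,
                                                  geosse_params=p, rho=rho))
        f1 = list(sf.values()).count(1) / len(sf)
        s1 = list(ss.values()).count(1) / len(ss)
        assert s1 < f1  # tropical endemics preferentially dropped

    def test_tip_state_coding_in_paper_convention(self):
        p = bd.GeoSSEParams(0.3, 0.2, 0.05, 0.05, 0.05, 0.1, 0.1)
        _, states = bd.sim_geosse_tree(bd.SimConfig(seed=13, n_taxa=50,
                                                    geosse_params=p))
        assert set(states.values()) <= {0, 1, 2}


class TestGridWorld:
    def test_seed_determinism(self):
        w1 = bd.sim_grid_world(10, 10, n_species=50, seed=4)
        w2 = bd.sim_grid_world(10, 10, n_species=50, seed=4)
        assert w1.ranges == w2.ranges
        assert w1.biomes.cell_biome == w2.biomes.cell_biome

    def test_band_carries_tropical_codes(self):
        w = bd.sim_grid_world(10, 6, tropical_rows=0.3, n_species=20, seed=1)
        for cell, (x, y) in w.coords.items():
            code = w.biomes.cell_biome[cell]
            assert (code in w.biomes.tropical) == (y < 3)

    def test_zero_gradient_uniform_rows(self):
        # per-row species incidence is a sum of independent per-species
        # indicators, so the goodness-of-fit test is well calibrated
        w = bd.sim_grid_world(10, 10, n_species=500, gradient_strength=0.0,
                              seed=6)
        counts = np.zeros(10)
        for cells in w.ranges.values():
            for r in {int(w.coords[c][1]) for c in cells}:
                counts[r] += 1
        assert stats.chisquare(counts).pvalue > 0.01

    def test_strong_gradient_enriches_tropics(self):
        for seed in range(20):
            w = bd.sim_grid_world(12, 8, tropical_rows=0.25, n_species=150,
                                  gradient_strength=6.0, seed=seed)
            m = bd.build_community_matrix(w.ranges, w.grid)
            sr = bd.richness(m, by="cell")
            trop = [sr[c] for c, (x, y) in w.coords.items() if y < 3]
            nont = [sr[c] for c, (x, y) in w.coords.items() if y >= 3]
            assert np.mean(trop) > np.mean(nont)

    def test_roundtrip_state_coding_matches_truth(self):
        w = bd.sim_grid_world(14, 10, n_species=200, seed=9)
        coded = bd.code_tip_states(w.ranges, w.biomes)
        assert coded == w.true_states

    def test_every_species_has_a_range(self):
        w = bd.sim_grid_world(6, 6, n_species=100, seed=11)
        assert len(w.ranges) == 100
        assert all(len(c) >= 1 for c in w.ranges.values())

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            bd.sim_grid_world(0, 5, n_species=10, seed=1)
        with pytest.raises(ValueError):
            bd.sim_grid_world(5, 5, tropical_rows=1.5, n_species=10, seed=1)
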