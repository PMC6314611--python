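"""Synthetic-data generator: determinism, truth construction, sampling law."""

import numpy as np
import pytest
from scipy import stats

import tickenm
from tickenm.occurrences import filter_uncertainty
from tickenm.synthetic import generate_futures


class TestGenerateClimate:
    def test_layers_standardized_and_shaped(self, env6):
        assert env6.shape == (50, 50)
        assert len(env6.names) == 6
        for arr in env6.layers.values():
            assert arr.std() == pytest.approx(1.0, abs=1e-9)
            assert arr.mean() == pytest.approx(0.0, abs=1e-9)

    def test_same_seed_bit_identical(self):
        a = tickenm.generate_climate(20, 30, ["a", "b"], 3.0, seed=42)
        b = tickenm.generate_climate(20, 30, ["a", "b"], 3.0, seed=42)
        for name in a.names:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_high_smoothness_approaches_pure_gradient(self):
        env = tickenm.generate_climate(40, 40, ["a", "b"], smoothness=200.0, seed=0)
        x = env.layers["a"]
        # neighbor correlation -> 1 for a near-deterministic smooth field
        r = np.corrcoef(x[:-1].ravel(), x[1:].ravel())[0, 1]
        assert r > 0.999

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            tickenm.generate_climate(5, 50, ["a", "b"], 3.0, seed=0)
        with pytest.raises(ValueError):
            tickenm.generate_climate(50, 50, ["only_one"], 3.0, seed=0)


class TestVirtualSpecies:
    def test_truth_bounded_and_normalized(self, species, env6):
        t = species.truth_grid
        assert np.all((t >= 0) & (t <= 1))
        assert t[env6.mask].max() == pytest.approx(1.0)

    def test_single_var_closed_form(self, env6):
        sp = tickenm.make_virtual_species(env6, ["var01"], {"var01": 0.0}, {"var01": 1.0})
        x = env6.layers["var01"]
        expected = np.exp(-(x**2) / 2.0)
        expected = expected / expected[env6.mask].max()
        np.testing.assert_allclose(sp.truth_grid[env6.mask], expected[env6.mask], rtol=1e-12)

    def test_infinite_breadth_is_flat(self, env6):
        sp = tickenm.make_virtual_species(env6, ["var01"], {"var01": 0.0}, {"var01": 1e9})
        np.testing.assert_allclose(sp.truth_grid[env6.mask], 1.0, atol=1e-9)

    def test_unknown_variable_and_bad_breadth(self, env6):
        with pytest.raises(KeyError):
            tickenm.make_virtual_species(env6, ["nope"], {"nope": 0}, {"nope": 1})
        with pytest.raises(ValueError):
            tickenm.make_virtual_species(env6, ["var01"], {"var01": 0}, {"var01": 0.0})


class TestSampleOccurrences:
    def test_degenerate_support(self, env6):
        truth = np.zeros(env6.shape)
        truth[10, 20] = 1.0
        sp = tickenm.VirtualSpecies(["var01"], {}, {}, truth, env6)
        occ = tickenm.sample_occurrences(sp, 25, seed=0)
        r, c = env6.transform.index_of(*occ.lonlat())
        assert (r == 10).all() and (c == 20).all()

    def test_cell_frequencies_track_truth(self, env6):
        # a peaked species: at n=2000 the per-cell Poisson counting noise
        # must not swamp the truth signal, which requires concentrated mass
        sp = tickenm.make_virtual_species(
            env6, ["var01", "var03"],
            optima={"var01": 0.5, "var03": -0.3},
            breadths={"var01": 0.25, "var03": 0.25},
        )
        occ = tickenm.sample_occurrences(sp, 2000, seed=3)
        r, c = env6.transform.index_of(*occ.lonlat())
        counts = np.zeros(sp.truth_grid.shape)
        np.add.at(counts, (r, c), 1)
        rho = stats.pearsonr(counts.ravel(), sp.truth_grid.ravel()).statistic
        assert rho > 0.9

    def test_sampling_law_chi_square(self, species):
        """Occurrence density per cell converges to truth/sum(truth)."""
        occ = tickenm.sample_occurrences(species, 10_000, seed=4)
        r, c = species.env.transform.index_of(*occ.lonlat())
        counts = np.zeros(species.truth_grid.shape)
        np.add.at(counts, (r, c), 1)
        p = species.truth_grid / species.truth_grid.sum()
        # pool cells with small expectation to keep the chi-square valid
        exp = p.ravel() * 10_000
        obs = counts.ravel()
        big = exp >= 5
        obs_pooled = np.append(obs[big], obs[~big].sum())
        exp_pooled = np.append(exp[big], exp[~big].sum())
        stat, pval = stats.chisquare(obs_pooled, exp_pooled)
        assert pval > 0.01

    def test_uncertainty_law_exercises_filter(self, species):
        occ = tickenm.sample_occurrences(species, 5000, seed=5)
        kept = filter_uncertainty(occ, 10_000)
        frac = len(kept) / len(occ)
        assert 0.85 < frac < 0.95  # ~90% retained by design of the default law
        all_high = tickenm.sample_occurrences(
            species, 50, uncertainty_law=lambda rng, n: np.full(n, 12_000.0), seed=6
        )
        assert len(filter_uncertainty(all_high, 10_000)) == 0

    def test_all_zero_truth_rejected(self, env6):
        sp = tickenm.VirtualSpecies(["var01"], {}, {}, np.zeros(env6.shape), env6)
        with pytest.raises(ValueError):
            tickenm.sample_occurrences(sp, 5, seed=0)


class TestGenerateFutures:
    def test_counts_and_registration(self, env6):
        deltas = {
            "rcp45": {v: 0.5 for v in env6.names},
            "rcp85": {v: 1.0 for v in env6.names},
        }
        scen = generate_futures(env6, n_gcm=4, scenario_deltas=deltas, seed=0)
        assert len(scen.futures) == 8  # 4 GCMs x 2 scenarios
        for stack in scen.futures.values():
            assert stack.same_grid(env6)

    def test_zero_deltas_zero_perturbation_identity(self, env6):
        deltas = {"none": {v: 0.0 for v in env6.names}}
        scen = generate_futures(env6, 2, deltas, seed=0, perturbation_sd=0.0)
        for stack in scen.futures.values():
            for name in env6.names:
                np.testing.assert_array_equal(stack.layers[name], env6.layers[name])

    def test_larger_delta_shifts_more(self, env6):
        deltas = {
            "rcp45": {v: 0.5 for v in env6.names},
            "rcp85": {v: 1.0 for v in env6.names},
        }
        scen = generate_futures(env6, 2, deltas, seed=1)
        for g in scen.gcms:
            for v in env6.names:
                s45 = np.abs(scen.futures[(g, "rcp45")].layers[v] - env6.layers[v]).mean()
                s85 = np.abs(scen.futures[(g, "rcp85")].layers[v] - env6.layers[v]).mean()
                assert s85 > s45

    def test_delta_mismatch_rejected(self, env6):
        with pytest.raises(ValueError):
            generate_futures(env6, 1, {"x": {"var01": 1.0}}, seed=0)
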