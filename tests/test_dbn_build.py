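"""DBN construction: structure, discretization, sampling, CPT counting."""

import numpy as np
import pytest

from compdbn.dbn_build import (build_dbn, count_cpts, dbn_from_json,
                               dbn_to_json, derive_structure,
                               make_discretization, required_samples,
                               sample_trajectories)
from compdbn.model_core import ModelError, build_network
from compdbn.ode_sim import TimeGrid
from compdbn.synthetic_data import three_species_cascade, two_species_decay


class TestRequiredSamples:
    @pytest.mark.parametrize("I,u,K,expected", [
        (5, 3, 5, 625), (5, 0, 7, 7), (6, 2, 5, 180)])
    def test_coverage_heuristic(self, I, u, K, expected):
        assert required_samples(I, u, K) == expected

    def test_cap_guard(self):
        with pytest.raises(ModelError, match="cap"):
            required_samples(5, 71, 5)
        assert required_samples(5, 12, 5, cap=10 ** 10) == 5 * 5 ** 12


class TestStructure:
    def test_decay_parent_rule(self):
        net = two_species_decay()
        s = derive_structure(net)
        assert set(s.parents["A"]) == {"A", "k1"}
        assert s.parents["k1"] == ("k1",)  # parameter: self only
        assert set(s.parents["B"]) == {"A", "B", "k1"}

    def test_chain_parents(self):
        net = three_species_cascade()
        s = derive_structure(net)
        assert set(s.parents["S2"]) == {"S1", "S2", "k1", "k2", "k3"}

    def test_every_parameter_has_single_self_edge(self, complement):
        s = derive_structure(complement)
        for p in s.parameter_nodes:
            assert s.parents[p] == (p,)


class TestDiscretization:
    def test_parameter_equal_width(self):
        d = make_discretization(param_bounds={"k": (0.0, 10.0)})
        assert d.boundaries["k"] == pytest.approx([0, 2, 4, 6, 8, 10])

    def test_variable_quantiles_of_uniform(self, rng):
        vals = rng.uniform(0.0, 1.0, 60000)
        d = make_discretization(variable_values={"x": vals})
        inner = d.boundaries["x"][1:-1]
        assert inner == pytest.approx(np.arange(1, 6) / 6.0, abs=0.02)

    def test_constant_variable_degenerate(self):
        d = make_discretization(variable_values={"x": np.zeros(100)})
        assert "x" in d.degenerate
        assert d.n_intervals("x") == 1

    def test_out_of_range_values_clamped(self):
        d = make_discretization(param_bounds={"k": (0.0, 10.0)})
        assert d.index("k", -3.0) == 0
        assert d.index("k", 42.0) == 4


class TestSampling:
    def _setup(self):
        net = two_species_decay()
        disc = make_discretization(param_bounds={"k1": net.params["k1"].bounds})
        disc.boundaries["A"] = np.array([100.0, 100.0])
        disc.boundaries["B"] = np.array([0.0, 0.0])
        disc.degenerate |= {"A", "B"}
        prior = {"k1": np.full(5, 0.2), "A": np.array([1.0]),
                 "B": np.array([1.0])}
        return net, prior, disc

    def test_seeded_reproducibility(self):
        net, prior, disc = self._setup()
        g = TimeGrid.regular(500, 100)
        e1 = sample_trajectories(net, prior, disc, 100, g, seed=7, batch=True)
        e2 = sample_trajectories(net, prior, disc, 100, g, seed=7, batch=True)
        assert np.array_equal(e1.values, e2.values)
        assert np.array_equal(e1.thetas, e2.thetas)

    def test_samples_inside_prior_support(self):
        net, prior, disc = self._setup()
        prior["k1"] = np.array([0.0, 0.0, 1.0, 0.0, 0.0])  # third interval
        g = TimeGrid.regular(500, 100)
        e = sample_trajectories(net, prior, disc, 200, g, seed=1, batch=True)
        b = disc.boundaries["k1"]
        k = e.thetas[:, e.param_names.index("k1")]
        assert np.all((k >= b[2]) & (k <= b[3]))

    def test_point_prior_gives_identical_trajectories(self):
        net, prior, disc = self._setup()
        disc.boundaries["k1"] = np.array([1e-3, 1e-3])
        disc.degenerate.add("k1")
        prior["k1"] = np.array([1.0])
        g = TimeGrid.regular(500, 100)
        e = sample_trajectories(net, prior, disc, 50, g, seed=1, batch=True)
        assert np.allclose(e.values, e.values[0], rtol=1e-7, atol=1e-9)


class TestCountCpts:
    def test_rows_normalised_and_parameter_identity(self):
        net = three_species_cascade()
        dbn = build_dbn(net, J=400, grid=TimeGrid.regular(1000, 200), seed=2,
                        batch=True)
        for node, cpt in dbn.cpts.items():
            for codes, probs, supp in cpt.rows:
                assert probs.sum(axis=1) == pytest.approx(1.0, abs=1e-9)
        for p in dbn.structure.parameter_nodes:
            codes, probs, _ = dbn.cpts[p].rows[0]
            n = dbn.n_intervals(p)
            assert np.array_equal(probs, np.eye(n))

    def test_deterministic_decay_point_masses(self):
        """Point parameter prior + fixed initial state: every stored CPT row
        is a point mass, and the coded path matches the direct simulation."""
        from compdbn.ode_sim import simulate

        net = two_species_decay(k=1e-3)
        grid = TimeGrid.regular(1000, 100)
        disc = make_discretization(param_values={"k1": 1e-3})
        disc.boundaries["A"] = np.linspace(0.0, 100.0, 7)
        disc.boundaries["B"] = np.linspace(0.0, 100.0, 7)
        prior = {"k1": np.array([1.0]), "A": np.array([1.0]),
                 "B": np.array([1.0])}
        disc.boundaries["A" + ""] = disc.boundaries["A"]
        init_disc = make_discretization(param_values={"k1": 1e-3})
        init_disc.boundaries.update(
            {"A": np.array([100.0, 100.0]), "B": np.array([0.0, 0.0])})
        init_disc.degenerate |= {"A", "B"}
        ens = sample_trajectories(net, prior, init_disc, 60, grid, seed=3,
                                  batch=True)
        dbn = count_cpts(ens, derive_structure(net), disc)
        for node in ("A", "B"):
            for codes, probs, supp in dbn.cpts[node].rows:
                assert np.all(probs.max(axis=1) == pytest.approx(1.0))
        # the single interval path equals the direct simulation's coding
        tr = simulate(net, grid)
        for node in ("A", "B"):
            sim_codes = disc.index(node, tr.series(node))
            ens_codes = disc.index(node, ens.values[0,
                                                    ens.species_names.index(node)])
            assert np.array_equal(sim_codes, ens_codes)

    def test_serialization_round_trip(self, tmp_path):
        net = three_species_cascade()
        dbn = build_dbn(net, J=300, grid=TimeGrid.regular(800, 200), seed=5,
                        batch=True)
        path = tmp_path / "dbn.json"
        dbn_to_json(dbn, path)
        back = dbn_from_json(path)
        assert back.structure.parents == dbn.structure.parents
        assert back.sample_count == dbn.sample_count
        for node in dbn.cpts:
            for (c1, p1, s1), (c2, p2, s2) in zip(dbn.cpts[node].rows,
                                                  back.cpts[node].rows):
                assert np.array_equal(c1, c2)
                assert np.array_equal(p1, p2)
        for n, v in dbn.prior.items():
            assert np.array_equal(back.prior[n], v)

    def test_pure_function_of_seed(self):
        net = three_species_cascade()
        g = TimeGrid.regular(600, 200)
        d1 = build_dbn(net, J=250, grid=g, seed=11, batch=True)
        d2 = build_dbn(net, J=250, grid=g, seed=11, batch=True)
        for node in d1.cpts:
            for (c1, p1, _), (c2, p2, _) in zip(d1.cpts[node].rows,
                                                d2.cpts[node].rows):
                assert np.array_equal(c1, c2) and np.array_equal(p1, p2)
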