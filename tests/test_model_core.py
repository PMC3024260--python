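"""Reaction network construction, rate laws, conditions, affinity model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compdbn.model_core import (Condition, ModelError, apply_condition,
                                build_network, default_affinity_model,
                                fit_affinity, ode_rhs)
from compdbn.ode_sim import TimeGrid, simulate


def toy_spec():
    return {
        "name": "toy",
        "species": [{"name": "A", "initial": 3.0},
                    {"name": "B", "initial": 4.0},
                    {"name": "C", "initial": 0.0}],
        "parameters": [{"name": "k", "value": 2.0, "bounds": [0.1, 10.0]}],
        "reactions": [{"id": "r1", "reactants": ["A", "B"],
                       "products": ["C"],
                       "law": {"kind": "mass_action", "k": "k"}}],
    }


class TestBuildNetwork:
    def test_complement_structural_counts(self, complement):
        assert len(complement.species) == 42
        assert len(complement.reactions) == 45
        assert len(complement.params) == 85
        assert len(complement.params.unknown_names) == 71
        assert complement.params.n_known == 14

    def test_two_species_toy(self):
        spec = {"name": "t2",
                "species": [{"name": "A", "initial": 1.0},
                            {"name": "B", "initial": 0.0}],
                "parameters": [{"name": "k", "value": 1.0, "known": True}],
                "reactions": [{"id": "r1", "reactants": ["A"],
                               "products": ["B"],
                               "law": {"kind": "mass_action", "k": "k"}}]}
        net = build_network(spec)
        assert len(net.species) == 2 and len(net.reactions) == 1

    @pytest.mark.parametrize("mutate,match", [
        (lambda s: s["reactions"][0]["reactants"].append("Z"), "unknown species"),
        (lambda s: s["parameters"][0].update(value=-1.0), "negative"),
        (lambda s: s["reactions"].append(dict(s["reactions"][0])), "duplicate reaction"),
    ])
    def test_validation_errors(self, mutate, match):
        spec = toy_spec()
        mutate(spec)
        with pytest.raises(ModelError, match=match):
            build_network(spec)

    def test_count_mismatch_warns_for_non_complement(self):
        spec = toy_spec()
        spec["counts"] = {"species": 5, "reactions": 1, "parameters": 1,
                          "unknown": 1}
        with pytest.warns(UserWarning, match="declared counts"):
            build_network(spec)


class TestOdeRhs:
    def test_bimolecular_mass_action(self):
        net = build_network(toy_spec())
        rhs = ode_rhs(net)
        dx = rhs(np.array([3.0, 4.0, 0.0]), np.array([2.0]))
        assert dx == pytest.approx([-24.0, -24.0, 24.0])

    def test_michaelis_menten(self):
        spec = toy_spec()
        spec["species"] = [{"name": "S", "initial": 4.0},
                           {"name": "P", "initial": 0.0},
                           {"name": "E", "initial": 2.0}]
        spec["parameters"] = [{"name": "c", "value": 3.0, "known": True},
                              {"name": "ch", "value": 4.0, "known": True}]
        spec["reactions"] = [{"id": "r1", "reactants": ["S"],
                              "products": ["P"], "modifiers": ["E"],
                              "law": {"kind": "michaelis_menten",
                                      "c": "c", "c_half": "ch"}}]
        net = build_network(spec)
        dx = ode_rhs(net)(np.array([4.0, 0.0, 2.0]), np.array([3.0, 4.0]))
        assert dx[0] == pytest.approx(-3.0)  # 3*2*4/(4+4)
        assert dx[2] == 0.0                   # enzyme unconsumed

    def test_zero_reactant_zero_rate(self):
        net = build_network(toy_spec())
        dx = ode_rhs(net)(np.array([0.0, 4.0, 0.0]), np.array([2.0]))
        assert np.all(dx == 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(x=st.lists(st.floats(0, 1e4), min_size=3, max_size=3),
           k=st.floats(0, 1e3))
    def test_mass_action_rate_nonnegative(self, x, k):
        """Non-negative states and constants never produce a negative rate
        (consumption of a species is bounded by producing reactions)."""
        net = build_network(toy_spec())
        dx = ode_rhs(net)(np.array(x), np.array([k]))
        assert dx[2] >= 0.0  # pure product

    def test_unresolved_parameter_raises(self):
        spec = toy_spec()
        del spec["parameters"][0]["value"]
        net = build_network(spec)
        with pytest.raises(ModelError, match="UNKNOWN"):
            net.params.values_vector()


class TestAffinityModel:
    def test_hundredfold_inflammation_ratio(self, affinity):
        assert affinity.fold_change() == pytest.approx(100.0, rel=0.01)

    def test_constant_anchor_table_gives_constant_one(self):
        anchors = [(ph, 2.5, 1.0) for ph in (5.5, 6.0, 6.5, 7.0, 7.4)]
        m = fit_affinity(anchors)
        for ph in np.linspace(5.5, 7.4, 7):
            assert m.value(ph, 2.5) == pytest.approx(1.0, abs=1e-9)

    def test_known_cubic_recovered(self):
        coef = np.poly1d([2.0, -30.0, 140.0, -180.0])  # positive on domain
        anchors = [(ph, 2.5, float(coef(ph)))
                   for ph in (5.5, 5.9, 6.3, 6.8, 7.4)]
        m = fit_affinity(anchors)
        ref = coef(7.4)
        for ph in (5.6, 6.1, 7.0):
            assert m.value(ph, 2.5) == pytest.approx(coef(ph) / ref, rel=1e-8)

    def test_monotone_nonincreasing_in_ph(self, affinity):
        for ca in (2.0, 2.5):
            vals = [affinity.value(ph, ca) for ph in np.linspace(5.5, 7.4, 60)]
            assert np.all(np.diff(vals) <= 0)
            assert min(vals) > 0

    def test_insufficient_anchors(self):
        with pytest.raises(ModelError, match="anchors"):
            fit_affinity([(7.4, 2.5, 1.0), (6.5, 2.5, 2.0)])


class TestApplyCondition:
    def test_reference_condition_is_identity(self, complement, affinity):
        net = apply_condition(complement, Condition(), affinity)
        for name in complement.params:
            assert net.params[name].value == pytest.approx(
                complement.params[name].value)
        assert np.allclose(net.initial_state(), complement.initial_state())

    def test_inflammation_scales_crosstalk_hundredfold(self, complement,
                                                       affinity):
        net = apply_condition(complement, Condition(pH=6.5, calcium=2.0),
                              affinity)
        ratio = net.params["kd01_1"].value / complement.params["kd01_1"].value
        assert ratio == pytest.approx(100.0, rel=0.01)

    def test_knockout_d_removes_only_tagged_decay(self, complement, affinity):
        net = apply_condition(complement,
                              Condition(knockouts=frozenset({"d"})), affinity)
        active = {r.id for r in net.active_reactions}
        tagged = {r.id for r in complement.reactions_with_tag("C4BP-d")}
        assert tagged and not (tagged & active)
        # natural decay (kt03_1) retained
        natural = [r for r in net.active_reactions
                   if r.rate_law.k == "kt03_1"]
        assert natural

    def test_depletion_zeroes_initial(self, complement, affinity):
        net = apply_condition(
            complement, Condition(depleted=frozenset({"L-ficolin"})), affinity)
        i = net.species_index("Lfic")
        assert net.species[i].initial_concentration == 0.0

    def test_unknown_depletion_rejected(self, complement, affinity):
        with pytest.raises(ModelError, match="deplete"):
            apply_condition(complement,
                            Condition(depleted=frozenset({"C9"})), affinity)

    def test_branch_suppression_zeroes_other_branch(self, complement, affinity):
        """PC initiation: every lectin-branch rate is identically zero."""
        net = apply_condition(complement, Condition(initiation="PC"), affinity)
        active = {r.id for r in net.active_reactions}
        lectin = {r.id for r in complement.reactions_with_tag("lectin")}
        ampg = {r.id for r in
                complement.reactions_with_tag("amplification-GlcNAc")}
        assert not ((lectin | ampg) & active)
        i = net.species_index("GlcNAc")
        assert net.species[i].initial_concentration == 0.0

    def test_suppression_and_knockout_commute(self, complement, affinity):
        c1 = Condition(initiation="PC", knockouts=frozenset({"b"}))
        a = apply_condition(complement, c1, affinity)
        # apply in two steps, in both orders
        b = apply_condition(
            apply_condition(complement, Condition(initiation="PC"), affinity),
            Condition(knockouts=frozenset({"b"})), affinity)
        c = apply_condition(
            apply_condition(complement, Condition(knockouts=frozenset({"b"})),
                            affinity),
            Condition(initiation="PC"), affinity)
        assert {r.id for r in a.active_reactions} \
            == {r.id for r in b.active_reactions} \
            == {r.id for r in c.active_reactions}

    def test_conservation_groups_hold_in_simulation(self, complement, affinity):
        net = apply_condition(complement, Condition(pH=6.5, calcium=2.0),
                              affinity)
        tr = simulate(net, TimeGrid.regular(3600, 400))
        x0 = net.initial_state()
        idx = {s: i for i, s in enumerate(net.species_names)}
        for group, members in net.conservation.items():
            w = np.zeros(len(x0))
            for sp, wt in members.items():
                w[idx[sp]] = wt
            totals = w @ tr.values
            assert totals == pytest.approx(w @ x0, rel=1e-6), group
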