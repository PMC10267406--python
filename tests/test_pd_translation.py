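"""PD → activity-flow reduction rules and logic inference."""

import itertools

import pytest

from boolpath import (PDGraph, Species, Reaction, apply_reduction_rules,
                      infer_logic, translate, read_pd_text, write_pd_text)


def pd(species, reactions):
    return PDGraph([Species(**s) if isinstance(s, dict) else s
                    for s in species], reactions)


class TestReductionRules:
    def test_rule1_receptor_ligand(self):
        """Receptor–ligand association: the receptor reactant is removed,
        the reaction's modifier stays attached."""
        g = pd([{"id": "R", "receptor": True}, {"id": "L"},
                {"id": "RL"}, {"id": "M"}],
               [Reaction("a1", "association", ("R", "L"), ("RL",),
                         (("M", "+"),))])
        reduced, trace = apply_reduction_rules(g)
        (r,) = reduced.reactions
        assert r.reactants == ("L",)
        assert r.modifiers == (("M", "+"),)
        assert [step[0] for step in trace.applied] == [1]
        assert "R" not in [s.id for s in reduced.species]

    def test_rule2_protein_association(self):
        """Two-protein association: reactants removed, modifier linked
        directly to the complex product."""
        g = pd([{"id": "A"}, {"id": "B"}, {"id": "AB"}, {"id": "M"}],
               [Reaction("a1", "association", ("A", "B"), ("AB",),
                         (("M", "+"),))])
        reduced, trace = apply_reduction_rules(g)
        (r,) = reduced.reactions
        assert r.reactants == ()
        assert r.modifiers == (("M", "+"),)
        assert 2 in [step[0] for step in trace.applied]
        net = infer_logic(reduced)
        assert str(net.functions["AB"]) == "M"

    def test_rule3_inactive_single_reaction_species(self):
        """An inactive species seen in exactly one reaction disappears."""
        g = pd([{"id": "X_inactive", "active": False}, {"id": "K"},
                {"id": "X"}],
               [Reaction("r1", "state_transition", ("X_inactive",), ("X",),
                         (("K", "+"),))])
        reduced, trace = apply_reduction_rules(g)
        assert "X_inactive" not in [s.id for s in reduced.species]
        assert reduced.reactions[0].reactants == ()
        assert (3, "r1", ("X_inactive",), ()) in trace.applied

    def test_rule3_keeps_multi_reaction_inactive_species(self):
        g = pd([{"id": "X0", "active": False}, {"id": "X"}, {"id": "Y"}],
               [Reaction("r1", "state_transition", ("X0",), ("X",)),
                Reaction("r2", "state_transition", ("X0",), ("Y",))])
        reduced, _ = apply_reduction_rules(g)
        assert "X0" in [s.id for s in reduced.species]

    def test_rule4_transport_same_biomolecule(self):
        """Transport between compartments collapses onto the product and
        re-links the donor's other reactions."""
        g = pd([{"id": "P_cyto", "name": "P", "compartment": "cytosol"},
                {"id": "P_nuc", "name": "P", "compartment": "nucleus"},
                {"id": "T"}],
               [Reaction("t1", "transport", ("P_cyto",), ("P_nuc",)),
                Reaction("r1", "state_transition", ("P_cyto",), ("T",))])
        reduced, trace = apply_reduction_rules(g)
        assert [s.id for s in reduced.species] == ["P_nuc", "T"]
        (r,) = reduced.reactions
        assert r.id == "r1" and r.reactants == ("P_nuc",)
        assert (4, "t1", ("P_cyto",), (("P_cyto", "P_nuc"),)) in trace.applied

    def test_reduction_never_increases_node_count(self):
        g = pd([{"id": "R", "receptor": True}, {"id": "L"}, {"id": "RL"},
                {"id": "X0", "active": False}, {"id": "X"}],
               [Reaction("a1", "association", ("R", "L"), ("RL",)),
                Reaction("r1", "state_transition", ("X0",), ("X",))])
        reduced, _ = apply_reduction_rules(g)
        assert len(reduced.species) <= len(g.species)

    def test_trace_removes_each_species_once(self):
        g = pd([{"id": "R", "receptor": True}, {"id": "L"}, {"id": "RL"}],
               [Reaction("a1", "association", ("R", "L"), ("RL",))])
        _, trace = apply_reduction_rules(g)
        removed = trace.removed_species()
        assert len(removed) == len(set(removed))


class TestLogicInference:
    def test_tau_phosphorylation_fragment(self):
        """Kinase-complex reactant + negative isomerase modifier give
        product = activator AND NOT inhibitor, at all 4 input patterns."""
        g = pd([{"id": "CDK5_p25"}, {"id": "PIN1"}, {"id": "MAPTP"}],
               [Reaction("r1", "state_transition", ("CDK5_p25",),
                         ("MAPTP",), (("PIN1", "-"),))])
        net, _ = translate(g)
        for c, p in itertools.product((0, 1), repeat=2):
            state = tuple(
                {"CDK5_p25": c, "PIN1": p, "MAPTP": 0}[x] for x in net.nodes)
            assert net.evaluate("MAPTP", state) == int(c and not p)

    def test_parallel_routes_disjoin(self):
        g = pd([{"id": "A"}, {"id": "B"}, {"id": "P"}],
               [Reaction("r1", "state_transition", ("A",), ("P",)),
                Reaction("r2", "state_transition", ("B",), ("P",))])
        net = infer_logic(g)
        assert str(net.functions["P"]) == "A | B"

    def test_conjunction_with_two_inhibitors_truth_table(self):
        """P = (A AND B) AND NOT (I1 OR I2), checked over all 16 rows."""
        g = pd([{"id": "A"}, {"id": "B"}, {"id": "I1"}, {"id": "I2"},
                {"id": "P"}],
               [Reaction("r1", "state_transition", ("A", "B"), ("P",),
                         (("I1", "-"), ("I2", "-")))])
        net = infer_logic(g)
        for a, b, i1, i2 in itertools.product((0, 1), repeat=4):
            env = {"A": a, "B": b, "I1": i1, "I2": i2, "P": 0}
            state = tuple(env[x] for x in net.nodes)
            assert net.evaluate("P", state) == int(
                (a and b) and not (i1 or i2))

    def test_inhibitor_modes_differ_on_multi_route_targets(self):
        # dominant: any route's inhibitor vetoes all routes; or: per-route
        g = pd([{"id": "A"}, {"id": "B"}, {"id": "I"}, {"id": "P"}],
               [Reaction("r1", "state_transition", ("A",), ("P",),
                         (("I", "-"),)),
                Reaction("r2", "state_transition", ("B",), ("P",))])
        dom = infer_logic(g, inhibitor_mode="dominant")
        per = infer_logic(g, inhibitor_mode="or")
        env = {"A": 0, "B": 1, "I": 1, "P": 0}
        state = tuple(env[x] for x in dom.nodes)
        assert dom.evaluate("P", state) == 0  # vetoed globally
        assert per.evaluate("P", state) == 1  # route via B unaffected

    def test_unproduced_species_become_free_inputs(self):
        g = pd([{"id": "A"}, {"id": "P"}],
               [Reaction("r1", "state_transition", ("A",), ("P",))])
        net = infer_logic(g)
        assert net.inputs == ["A"]

    def test_regulatorless_product_warns_and_becomes_input(self):
        g = pd([{"id": "A"}, {"id": "B"}, {"id": "AB"}],
               [Reaction("a1", "association", ("A", "B"), ("AB",))])
        reduced, _ = apply_reduction_rules(g)
        with pytest.warns(UserWarning, match="no\\s+regulators"):
            net = infer_logic(reduced)
        assert "AB" in net.inputs


class TestPdText:
    def test_round_trip(self):
        g = pd([{"id": "R", "receptor": True},
                {"id": "L", "name": "ligand", "compartment": "ecm"},
                {"id": "RL"}, {"id": "M", "active": False,
                               "modifications": ("phosphorylated",)}],
               [Reaction("a1", "association", ("R", "L"), ("RL",),
                         (("M", "-"),))])
        back = read_pd_text(write_pd_text(g))
        assert back.species == g.species
        assert back.reactions == g.reactions

    def test_reaction_without_product_rejected(self):
        with pytest.raises(ValueError, match="no products"):
            pd([{"id": "A"}], [Reaction("r1", "state_transition", ("A",), ())])

    def test_undeclared_participant_rejected(self):
        with pytest.raises(ValueError, match="undeclared"):
            pd([{"id": "A"}],
               [Reaction("r1", "state_transition", ("A",), ("Z",))])
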