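"""Attractor search strategies vs exhaustive / STG ground truth."""

import pytest

from boolpath import (read_rules, exhaustive_sync, sat_steady_states,
                      sat_cycles, decomposition_search, heuristic_search,
                      async_random_walk)
from boolpath.attractors import dedupe
from boolpath import async_step

from conftest import (make_random_networks, oracle_sync_attractors,
                      oracle_async_terminal_sccs)

ENSEMBLE = make_random_networks(20, max_n=9, seed0=300)
IDS = [n.metadata["name"] for n in ENSEMBLE]


class TestExhaustive:
    def test_toggle_landscape(self, toggle):
        atts = exhaustive_sync(toggle)
        kinds = sorted((a.kind, a.basin) for a in atts)
        assert kinds == [("cycle", 2), ("steady", 1), ("steady", 1)]

    def test_constant_network_single_fixed_point(self):
        net = read_rules("A, 1\nB, 0\nC, 1\n")
        (att,) = exhaustive_sync(net)
        assert att.kind == "steady" and att.states == ((1, 0, 1),)
        assert att.basin == 8

    def test_cap(self, toggle):
        with pytest.raises(ValueError, match="cap"):
            exhaustive_sync(toggle, cap=1)

    @pytest.mark.parametrize("net", ENSEMBLE, ids=IDS)
    def test_matches_stepwise_oracle_with_basins(self, net):
        expected = oracle_sync_attractors(net)
        atts = exhaustive_sync(net)
        got = {frozenset(a.states): a.basin for a in atts}
        assert got == expected
        assert sum(a.basin for a in atts) == 2 ** len(net)


class TestSat:
    def test_toggle_fixed_points(self, toggle):
        assert sat_steady_states(toggle) == [(0, 1), (1, 0)]

    def test_no_fixed_point_is_unsat(self):
        assert sat_steady_states(read_rules("A, !A")) == []

    @pytest.mark.parametrize("net", ENSEMBLE, ids=IDS)
    def test_equals_exhaustive_fixed_points(self, net):
        expected = sorted(a.states[0] for a in exhaustive_sync(net)
                          if a.kind == "steady")
        assert sat_steady_states(net) == expected

    def test_single_negation_two_cycle(self):
        (att,) = sat_cycles(read_rules("A, !A"), 2)
        assert att.states == ((0,), (1,))

    def test_toggle_two_cycle(self, toggle):
        (att,) = sat_cycles(toggle, 2)
        assert att.states == ((0, 0), (1, 1))

    def test_rejects_length_one(self, toggle):
        with pytest.raises(ValueError):
            sat_cycles(toggle, 1)

    @pytest.mark.parametrize("L", [2, 3, 4])
    @pytest.mark.parametrize("net", ENSEMBLE[:8], ids=IDS[:8])
    def test_cycles_match_exhaustive(self, net, L):
        expected = sorted(a.states for a in exhaustive_sync(net)
                          if a.kind == "cycle" and len(a.states) == L)
        got = sorted(a.states for a in sat_cycles(net, L))
        assert got == expected


class TestDecomposition:
    def test_independent_toggles_compose(self):
        net = read_rules("A, !B\nB, !A\nC, !D\nD, !C\n")
        atts = decomposition_search(net)
        steadies = [a for a in atts if a.kind == "steady"]
        assert len(steadies) == 4 and all(a.verified for a in steadies)

    def test_feedforward_chain_equals_exhaustive(self):
        net = read_rules("A, A\nB, A\nC, A & B\n")
        got = {a.key() for a in decomposition_search(net) if a.verified}
        expected = {a.key() for a in exhaustive_sync(net)}
        assert got == expected

    def test_interblock_cycle_yields_unverified_candidate(self):
        # B copies the oscillator A with a lag; composing the blocks
        # independently produces phase combinations the full synchronous
        # dynamics never realizes
        net = read_rules("A, !A\nB, A\n")
        atts = decomposition_search(net)
        assert any(not a.verified for a in atts)

    @pytest.mark.parametrize("net", ENSEMBLE[:10], ids=IDS[:10])
    def test_verified_flag_is_exact(self, net):
        """Verified candidates appear in the exhaustive ground truth;
        unverified candidates are exactly those absent from it."""
        truth = {a.key() for a in exhaustive_sync(net)}
        for cand in decomposition_search(net):
            assert cand.verified == (cand.key() in truth)


class TestHeuristic:
    def test_toggle_full_coverage(self, toggle):
        atts = heuristic_search(toggle, n_starts=100, seed=3)
        assert len(atts) == 3  # basins 1+1+2 over 4 states: all reachable

    def test_single_start_at_fixed_point(self):
        net = read_rules("A, 1")
        atts = heuristic_search(net, n_starts=1, seed=0)
        assert [a.states for a in atts] == [((1,),)]

    @pytest.mark.parametrize("net", ENSEMBLE, ids=IDS)
    def test_subset_of_exhaustive(self, net):
        truth = {a.key() for a in exhaustive_sync(net)}
        found = {a.key() for a in heuristic_search(net, 50, seed=5)}
        assert found <= truth


class TestAsyncWalk:
    def test_toggle_two_steady_no_complex(self, toggle):
        atts = async_random_walk(toggle, n_runs=50, seed=2)
        assert sorted(a.states[0] for a in atts) == [(0, 1), (1, 0)]
        assert all(a.kind == "steady" for a in atts)

    def test_repressilator_complex_attractor(self, repressilator):
        """The 3-node negative feedback loop cycles through the six
        non-fixed states as one terminal SCC."""
        atts = async_random_walk(repressilator, n_runs=30, max_steps=200,
                                 seed=4)
        (att,) = atts
        assert att.kind == "complex" and len(att.states) == 6

    def test_immediate_return_from_steady_start(self, toggle):
        # seeds that land on a steady state terminate the walk instantly
        atts = async_random_walk(toggle, n_runs=200, max_steps=1, seed=8)
        assert all(a.kind == "steady" for a in atts)

    @pytest.mark.parametrize("net", ENSEMBLE[:10], ids=IDS[:10])
    def test_certified_attractors_are_closed_and_true(self, net):
        truth = oracle_async_terminal_sccs(net)
        for att in async_random_walk(net, n_runs=200, max_steps=300, seed=6):
            assert att.certified
            assert frozenset(att.states) in truth
            for state in att.states:  # closure under every async move
                for node in net.nodes:
                    succ = async_step(net, state, node)
                    assert succ in set(att.states) or succ == state


def test_dedupe_is_deterministic():
    a = async_random_walk(read_rules("A, !B\nB, !A\n"), n_runs=30, seed=1)
    b = async_random_walk(read_rules("A, !B\nB, !A\n"), n_runs=30, seed=1)
    assert [x.key() for x in dedupe(a)] == [x.key() for x in dedupe(b)]


def test_cnf_backend_dimacs_and_unsat():
    """The CNF layer emits well-formed DIMACS and the solver certifies
    an unsatisfiable encoding (network with no fixed point)."""
    from boolpath import sat as satmod
    from boolpath.sat import CnfBuilder, to_dimacs, solve

    builder = CnfBuilder()
    x = builder.new_var("x")
    builder.add([x])
    builder.add([-x])
    text = to_dimacs(builder.n_vars, builder.clauses)
    assert text.splitlines()[0] == "p cnf 1 2"
    assert all(line.endswith(" 0") for line in text.splitlines()[1:])
    assert solve(builder.n_vars, builder.clauses) is None
    assert satmod.solve(1, [[1]]) == [1]
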