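"""Motif reduction, succession diagrams, deletion projection, restriction
spaces, motif-avoidant search, and the full attractor pipeline."""

import numpy as np
import pytest

from conftest import random_systems
from paritybn.expanded import build_parity_expanded_network
from paritybn.expressions import BoolFunc
from paritybn.motifs import find_stable_motifs
from paritybn.reduction import deletion_project, reduce_by_motif
from paritybn.stg import brute_force_attractors
from paritybn.succession import (
    Budget,
    build_succession_diagram,
    enumerate_attractors,
    find_motif_avoidant_attractors,
    terminal_restriction_space,
)
from paritybn.system import parse_bnet
from paritybn.transforms import parity_transform


class TestReduceByMotif:
    def test_worked_example_full_collapse(self, worked_example):
        red = reduce_by_motif(worked_example, frozenset({("A", 1), ("B", 1), ("C", 1)}))
        assert red.residual is None
        assert red.fixed_dict() == {"A": 1, "B": 1, "C": 1}
        assert worked_example.state_to_str(red.lift_state()) == "111"

    def test_cascade_reduction_to_bistable_pair(self, cascade):
        """Committing the mutual-activation switch fixes C and D and leaves
        a bistable system on E and F."""
        red = reduce_by_motif(cascade, frozenset({("A", 1), ("B", 1)}))
        assert red.fixed_dict() == {"A": 1, "B": 1, "C": 1, "D": 1}
        assert red.residual.variables == ("E", "F")
        sub_atts = brute_force_attractors(red.residual)
        assert len(sub_atts) == 2 and all(a.is_point for a in sub_atts)

    def test_single_self_activator(self):
        red = reduce_by_motif(parse_bnet("A, A"), frozenset({("A", 1)}))
        assert red.residual is None and red.fixed_dict() == {"A": 1}

    def test_non_module_rejected(self, worked_example):
        with pytest.raises(ValueError):
            reduce_by_motif(worked_example, frozenset({("C", 1)}))

    def test_attractors_in_trap_space_correspond(self):
        """Attractors inside the motif's trap space match the residual's
        attractors extended by the fixed values."""
        for sys in random_systems(seed=191, count=20, n_max=6):
            pen = build_parity_expanded_network(sys)
            for m in find_stable_motifs(pen):
                red = reduce_by_motif(sys, m.nodes, validate=False)
                inside = [
                    frozenset(a.states)
                    for a in brute_force_attractors(sys)
                    if all(
                        (next(iter(a.states)) >> sys.index(v)) & 1 == s
                        for v, s in red.fixed
                    )
                    and all(
                        all((x >> sys.index(v)) & 1 == s for v, s in red.fixed)
                        for x in a.states
                    )
                ]
                if red.residual is None:
                    lifted = [frozenset([red.lift_state()])]
                else:
                    lifted = [
                        frozenset(red.lift_state(x) for x in a.states)
                        for a in brute_force_attractors(red.residual)
                    ]
                assert sorted(map(sorted, inside)) == sorted(map(sorted, lifted))


class TestDeletionProjection:
    def test_copy_loop_collapses_to_self_activation(self):
        pm, proj = deletion_project(parse_bnet("A, B\nB, A"), targets=["B"])
        assert proj.variables == ("A",)
        assert proj.functions["A"] == BoolFunc.variable("A")
        # point attractors lift to 00 and 11
        assert {pm.parent.state_to_str(pm.lift_state(s)) for s in (0, 1)} == {
            "00",
            "11",
        }

    def test_negative_loop_projects_to_self_negation(self):
        pm, proj = deletion_project(parse_bnet("A, !B\nB, A"), targets=["B"])
        assert proj.functions["A"] == BoolFunc.parse("!A")
        assert len(brute_force_attractors(proj)) == 1  # the 2-state oscillation

    def test_self_regulating_variable_protected(self):
        with pytest.raises(ValueError):
            deletion_project(parse_bnet("A, A\nB, A"), targets=["A"])

    def test_constant_prioritized_and_projection_stops_at_self_regulation(self):
        pm, proj = deletion_project(parse_bnet("A, 1\nB, A | B\nC, B"))
        assert pm.deleted[0] == "A"  # constant functions go first
        # everything percolates: only the mandatory last variable remains
        assert proj.n == 1
        # deleting one toggle variable makes its partner self-regulating;
        # the downstream chain is then absorbed as well
        pm2, proj2 = deletion_project(parse_bnet("A, !B\nB, !A\nC, A\nD, C"))
        assert proj2.variables == ("B",)
        assert all(v in proj2.functions[v].inputs for v in proj2.variables)

    def test_order_independence_of_projection(self):
        sys = parse_bnet("A, B\nB, C\nC, D\nD, D")
        pm1, _ = deletion_project(sys, targets=["A", "B", "C"])
        pm2, _ = deletion_project(sys, targets=["C", "B", "A"])
        for s in (0, 1):
            assert pm1.lift_state(s) == pm2.lift_state(s)

    def test_point_attractor_preservation(self):
        """Deletion projection preserves point attractors through a bijection
        given by representative-state lifting."""
        for sys in random_systems(seed=201, count=30):
            pm, proj = deletion_project(sys)
            parent_points = {
                next(iter(a.states))
                for a in brute_force_attractors(sys)
                if a.is_point
            }
            lifted = {
                pm.lift_state(next(iter(a.states)))
                for a in brute_force_attractors(proj)
                if a.is_point
            }
            assert lifted == parent_points

    def test_complex_attractors_never_decrease(self):
        for sys in random_systems(seed=211, count=30):
            pm, proj = deletion_project(sys)
            n_parent = sum(
                1 for a in brute_force_attractors(sys) if not a.is_point
            )
            n_proj = sum(
                1 for a in brute_force_attractors(proj) if not a.is_point
            )
            assert n_proj >= n_parent

    def test_motif_activity_preserved(self):
        """A motif active in a parent attractor stays active (on its
        surviving variables) in the projected image."""
        for sys in random_systems(seed=221, count=20, n_max=6):
            pen = build_parity_expanded_network(sys)
            motifs = find_stable_motifs(pen)
            pm, proj = deletion_project(sys)
            pv = set(proj.variables)
            for a in brute_force_attractors(sys):
                proj_states = {pm.project_state(x) for x in a.states}
                for m in motifs:
                    active = all(
                        all((x >> sys.index(v)) & 1 == s for x in a.states)
                        for v, s in m.nodes
                    )
                    if active:
                        surviving = {(v, s) for v, s in m.nodes if v in pv}
                        assert all(
                            all((y >> proj.index(v)) & 1 == s for v, s in surviving)
                            for y in proj_states
                        )


class TestTerminalRestrictionSpace:
    def test_worked_example_predicate_and_states(self, worked_example):
        trs = terminal_restriction_space(worked_example)
        # R(X) = !X_C & (!X_A | !X_B)
        assert trs.predicate == BoolFunc.parse("!C & (!A | !B)")
        assert {worked_example.state_to_str(s) for s in trs.states} == {
            "000",
            "010",
            "100",
        }

    def test_contradictory_drivers_empty_space(self):
        trs = terminal_restriction_space(parse_bnet("A, A\nB, B"))
        assert trs.trivially_empty and trs.size() == 0

    def test_no_drivers_trivial_predicate(self):
        trs = terminal_restriction_space(parse_bnet("A, !B\nB, A"))
        assert trs.predicate == BoolFunc.constant(1)
        assert trs.size() == 4  # nothing excluded: no motifs either way


class TestMotifAvoidantSearch:
    def test_worked_example_oscillation(self, worked_example):
        pen = build_parity_expanded_network(worked_example)
        motifs = find_stable_motifs(pen)
        trs = terminal_restriction_space(worked_example, pen, motifs)
        (att,) = find_motif_avoidant_attractors(worked_example, trs, motifs)
        assert att.state_strings() == ["000", "010", "100"]
        assert att.fixed_variables() == {"C": 0}

    def test_identity_none(self):
        sys = parse_bnet("A, A\nB, B")
        trs = terminal_restriction_space(sys)
        assert find_motif_avoidant_attractors(sys, trs) == []

    def test_motif_free_oscillator_found(self):
        sys = parse_bnet("A, !B\nB, A")
        trs = terminal_restriction_space(sys)
        (att,) = find_motif_avoidant_attractors(sys, trs)
        assert len(att) == 4


class TestSuccessionDiagram:
    def test_worked_example_shape(self, worked_example):
        sd = build_succession_diagram(worked_example)
        assert sd.complete
        root = sd.nodes[frozenset()]
        assert len(root.motif_avoidant) == 1
        assert set(sd.graph.successors(frozenset())) == {
            frozenset({("A", 1), ("B", 1), ("C", 1)})
        }
        atts = sd.all_attractors()
        assert sorted(a.state_strings() for a in atts) == [
            ["000", "010", "100"],
            ["111"],
        ]

    def test_cascade_three_leaves_three_attractors(self, cascade):
        sd = build_succession_diagram(cascade)
        atts = sd.all_attractors()
        assert len(atts) == 3 and all(a.is_point for a in atts)
        assert sorted(a.state_strings()[0] for a in atts) == [
            "000001",
            "111101",
            "111110",
        ]

    def test_phase_switch_three_point_attractors(self, phase_switch):
        sd = build_succession_diagram(phase_switch)
        atts = sd.all_attractors()
        assert len(atts) == 3 and all(a.is_point for a in atts)

    def test_merging_of_commitment_orders(self, cascade):
        """Different motif orders reaching the same commitment share a node."""
        sd = build_succession_diagram(cascade)
        keys = list(sd.nodes)
        assert len(keys) == len(set(keys))
        # the E/F decision is reachable after A/B or directly: diamond merges
        assert sd.graph.in_degree(
            frozenset({("A", 1), ("B", 1), ("E", 0), ("F", 1)})
        ) == 2

    def test_attractors_lie_in_their_nodes_trap_space(self):
        for sys in random_systems(seed=231, count=20, n_max=6):
            sd = build_succession_diagram(sys)
            for key, node in sd.nodes.items():
                for a in node.attractors + node.motif_avoidant:
                    for x in a.states:
                        for v, s in node.fixed.items():
                            assert (x >> sys.index(v)) & 1 == s

    def test_dot_export(self, worked_example):
        dot = build_succession_diagram(worked_example).to_dot()
        assert "root" in dot and "A=1" in dot


class TestEnumerateAttractors:
    def test_worked_example_exact(self, worked_example):
        rep = enumerate_attractors(worked_example)
        assert rep.exact and rep.count == 2

    def test_phase_switch_exact(self, phase_switch):
        rep = enumerate_attractors(phase_switch)
        assert rep.exact and rep.count == 3
        assert all(a.is_point for a in rep.attractors)

    def test_parity_consistency(self):
        for sys in random_systems(seed=241, count=15):
            full = (1 << sys.n) - 1
            rep = enumerate_attractors(sys)
            rep_p = enumerate_attractors(parity_transform(sys))
            flipped = {
                frozenset(x ^ full for x in a.states) for a in rep_p.attractors
            }
            assert flipped == {frozenset(a.states) for a in rep.attractors}

    def test_oracle_equivalence_sweep(self):
        """Exact mode equals the terminal-SCC oracle as sets of state-sets."""
        for sys in random_systems(seed=251, count=120):
            rep = enumerate_attractors(sys)
            assert rep.fully_resolved
            assert {frozenset(a.states) for a in rep.attractors} == {
                frozenset(a.states) for a in brute_force_attractors(sys)
            }

    def test_bounds_sandwich_under_tight_budget(self):
        """With budgets forcing the bound path, lower <= oracle <= upper."""
        tight = Budget(space_bits=2, succession_nodes=4)
        for sys in random_systems(seed=261, count=40, n_max=7):
            rep = enumerate_attractors(sys, tight)
            oracle = len(brute_force_attractors(sys))
            if rep.exact:
                assert rep.count == oracle
            else:
                assert rep.lower <= oracle
                if rep.upper is not None:
                    assert oracle <= rep.upper
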