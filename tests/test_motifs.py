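"""Stable motifs, trap spaces, LDOI/DOI, drivers, self-negation, Gardens of Eden."""

import pytest

from conftest import random_systems
from paritybn.expanded import build_parity_expanded_network, parity_image
from paritybn.motifs import (
    StableModule,
    compute_doi_exact,
    compute_ldoi,
    exhaustive_stable_modules,
    find_maximal_stable_modules,
    find_stable_motifs,
    garden_of_eden_spaces,
    is_self_negating,
    is_self_negating_exact,
    motif_trap_space,
    single_node_drivers,
)
from paritybn.stg import brute_force_attractors, build_stg
from paritybn.system import parse_bnet
from paritybn.transforms import parity_transform


def pen_of(sys):
    return build_parity_expanded_network(sys)


class TestStableMotifs:
    def test_worked_example_sole_motif(self, worked_example):
        res = find_stable_motifs(pen_of(worked_example))
        assert res.complete
        assert [sorted(m.nodes) for m in res] == [[("A", 1), ("B", 1), ("C", 1)]]
        assert all(m.is_motif for m in res)

    def test_mutual_inhibition_two_motifs(self):
        res = find_stable_motifs(pen_of(parse_bnet("A, !B\nB, !A")))
        assert {frozenset(m.nodes) for m in res} == {
            frozenset({("A", 1), ("B", 0)}),
            frozenset({("A", 0), ("B", 1)}),
        }

    def test_self_activation_both_layers(self):
        res = find_stable_motifs(pen_of(parse_bnet("A, A")))
        assert {frozenset(m.nodes) for m in res} == {
            frozenset({("A", 1)}),
            frozenset({("A", 0)}),
        }

    def test_pure_negative_feedback_has_none(self):
        assert len(find_stable_motifs(pen_of(parse_bnet("A, !B\nB, A")))) == 0

    def test_motifs_self_drive(self):
        """The vertex set of any stable motif logically drives itself."""
        for sys in random_systems(seed=81, count=30, n_max=6):
            pen = pen_of(sys)
            for m in find_stable_motifs(pen):
                assert m.nodes <= compute_ldoi(pen, m.nodes).ldoi

    def test_agreement_with_exhaustive_subset_oracle(self):
        for sys in random_systems(seed=91, count=30, n_max=5):
            pen = pen_of(sys)
            modules, _ = exhaustive_stable_modules(pen)
            minimal = {m for m in modules if not any(o < m for o in modules)}
            assert {frozenset(m.nodes) for m in find_stable_motifs(pen)} == minimal

    def test_motifs_map_under_parity(self):
        for sys in random_systems(seed=101, count=25, n_max=6):
            fwd = {frozenset(m.nodes) for m in find_stable_motifs(pen_of(sys))}
            par = {
                frozenset(m.nodes)
                for m in find_stable_motifs(pen_of(parity_transform(sys)))
            }
            assert par == {frozenset(parity_image(m)) for m in fwd}


class TestMaximalModules:
    def test_two_independent_switches(self):
        res = find_maximal_stable_modules(parse_bnet("A, A\nB, B"))
        assert len(res) == 4  # matches the 4 point attractors

    def test_worked_example_single_maximal(self, worked_example):
        res = find_maximal_stable_modules(worked_example)
        assert [sorted(m.nodes) for m in res] == [[("A", 1), ("B", 1), ("C", 1)]]

    def test_no_modules_in_negative_feedback(self):
        assert len(find_maximal_stable_modules(parse_bnet("A, !B\nB, A"))) == 0

    def test_agreement_with_exhaustive_oracle(self):
        for sys in random_systems(seed=111, count=30, n_max=5):
            _, maximal = exhaustive_stable_modules(pen_of(sys))
            got = {frozenset(m.nodes) for m in find_maximal_stable_modules(sys)}
            assert got == set(maximal)

    def test_count_lower_bounds_attractors(self):
        for sys in random_systems(seed=121, count=40):
            n_mod = len(find_maximal_stable_modules(sys))
            assert n_mod <= len(brute_force_attractors(sys))


class TestTrapSpaces:
    def test_motif_trap_space_values(self, worked_example):
        (m,) = find_stable_motifs(pen_of(worked_example))
        assert motif_trap_space(m).as_dict() == {"A": 1, "B": 1, "C": 1}

    def test_empty_module_rejected(self, worked_example):
        with pytest.raises(ValueError):
            StableModule(pen_of(worked_example), frozenset())

    def test_closure_under_dynamics(self):
        """No change-edge leaves a motif trap space; no change-edge enters a
        trap space of the time reversal (Garden-of-Eden duality)."""
        for sys in random_systems(seed=131, count=25, n_max=7):
            stg = build_stg(sys)
            pen = pen_of(sys)
            for m in find_stable_motifs(pen):
                space = motif_trap_space(m)
                inside = [s for s in stg.nodes if space.contains_state(sys, s)]
                for s in inside:
                    for t in stg.successors(s):
                        assert space.contains_state(sys, t)
            spaces, _ = garden_of_eden_spaces(sys)
            for space in spaces:
                inside = [s for s in stg.nodes if space.contains_state(sys, s)]
                for s in stg.nodes:
                    if not space.contains_state(sys, s):
                        for t in stg.successors(s):
                            assert not space.contains_state(sys, t)


class TestInfluence:
    def test_worked_example_ldoi_values(self, worked_example):
        pen = pen_of(worked_example)
        assert compute_ldoi(pen, {("C", 0)}).ldoi == frozenset()
        assert compute_ldoi(pen, {("A", 1)}).ldoi == frozenset()
        assert compute_ldoi(pen, {("C", 1)}).ldoi == {
            ("A", 1),
            ("B", 1),
            ("C", 1),
        }

    def test_inconsistent_source_rejected(self, worked_example):
        with pytest.raises(ValueError):
            compute_ldoi(pen_of(worked_example), {("A", 1), ("A", 0)})

    def test_doi_exact_worked_example(self, worked_example):
        res = compute_doi_exact(worked_example, {("C", 1)})
        assert res.doi == {("A", 1), ("B", 1), ("C", 1)}

    def test_doi_contradiction_for_pinned_negation(self):
        res = compute_doi_exact(parse_bnet("A, !A"), {("A", 1)})
        assert res.self_negating and res.contradictions == (("A", 0),)

    def test_ldoi_subset_of_doi(self):
        for sys in random_systems(seed=141, count=25, n_max=6):
            pen = pen_of(sys)
            for v in sys.variables:
                for s in (0, 1):
                    res = compute_doi_exact(sys, {(v, s)})
                    assert res.ldoi <= res.doi

    def test_attractor_confinement_for_singletons(self):
        """If an attractor holds (v, s) in some state, it holds DOI((v,s))
        fully in at least one state."""
        for sys in random_systems(seed=151, count=20, n_max=6):
            atts = brute_force_attractors(sys)
            for v in sys.variables:
                i = sys.index(v)
                for s in (0, 1):
                    doi = compute_doi_exact(sys, {(v, s)}).doi
                    for a in atts:
                        if any((x >> i) & 1 == s for x in a.states):
                            ok = any(
                                all(
                                    (x >> sys.index(n)) & 1 == val
                                    for n, val in doi
                                )
                                for x in a.states
                            )
                            assert ok


class TestDrivers:
    def test_worked_example_delta(self, worked_example):
        pen = pen_of(worked_example)
        motifs = find_stable_motifs(pen)
        assert single_node_drivers(pen, motifs) == {("C", 1)}

    def test_self_activation_drives_itself(self):
        pen = pen_of(parse_bnet("A, A"))
        assert single_node_drivers(pen, find_stable_motifs(pen)) == {
            ("A", 1),
            ("A", 0),
        }

    def test_no_motifs_no_drivers(self):
        pen = pen_of(parse_bnet("A, !B\nB, A"))
        assert single_node_drivers(pen, find_stable_motifs(pen)) == set()

    def test_driver_activity_forbidden_in_avoiding_attractors(self):
        """No attractor that keeps motif M inactive ever visits a state where
        a single-node driver of M is active."""
        for sys in random_systems(seed=161, count=20, n_max=6):
            pen = pen_of(sys)
            motifs = find_stable_motifs(pen)
            atts = brute_force_attractors(sys)
            for m in motifs:
                drivers = [
                    node
                    for node in pen.virtual_nodes
                    if m.nodes <= compute_ldoi(pen, {node}).ldoi
                ]
                space = motif_trap_space(m)
                for a in atts:
                    if all(not space.contains_state(sys, x) for x in a.states):
                        for x in a.states:
                            env = sys.state_env(x)
                            for n, s in drivers:
                                assert env[n] != s


class TestSelfNegation:
    def test_not_self_negating_when_ldoi_empty(self, worked_example):
        flag, _ = is_self_negating(pen_of(worked_example), {("C", 0)})
        assert not flag

    def test_negative_autoregulation_self_negates(self):
        flag, witness = is_self_negating(pen_of(parse_bnet("A, !A")), {("A", 1)})
        assert flag and witness == (("A", 0),)

    def test_motif_vertex_sets_never_self_negate(self):
        for sys in random_systems(seed=171, count=25, n_max=6):
            pen = pen_of(sys)
            for m in find_stable_motifs(pen):
                flag, _ = is_self_negating(pen, m.nodes)
                assert not flag
                assert not is_self_negating_exact(sys, m.nodes, max_subset=6)

    def test_ldoi_verdict_is_sound(self):
        """A positive LDOI verdict is always confirmed by the exact test."""
        for sys in random_systems(seed=181, count=20, n_max=5):
            pen = pen_of(sys)
            for v in sys.variables:
                for s in (0, 1):
                    flag, _ = is_self_negating(pen, {(v, s)})
                    if flag:
                        assert is_self_negating_exact(sys, {(v, s)}, max_subset=6)


class TestGardenOfEden:
    def test_phase_switch_three_sources(self, phase_switch):
        spaces, sources = garden_of_eden_spaces(phase_switch)
        assert len(sources) == 3

    def test_constant_one_variable(self):
        spaces, sources = garden_of_eden_spaces(parse_bnet("A, 1"))
        assert sources == [0]
        assert [sp.as_dict() for sp in spaces] == [{"A": 0}]

    def test_identity_has_no_sources(self):
        _, sources = garden_of_eden_spaces(parse_bnet("A, A\nB, B"))
        assert sources == []
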