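"""Succession diagrams and the attractor identification algorithm.

The algorithm recursively commits stable motifs: committing a motif fixes
its variables plus their LDOI and yields a residual system, repeated until
no motif remains.  The succession diagram is the DAG of cumulative motif
commitments (nodes keyed by the union of committed motif vertex sets, so
different orders reaching the same commitment merge).  Attractors appear in
two ways:

* at maximally reduced nodes: the fixed values are a point attractor when no
  variable remains; a motif-free residual contributes complex attractors
  found by exhaustive search of its (exclusion-pruned) state space;
* as *motif-avoidant* attractors at nodes whose residual still has motifs:
  complex attractors that never activate any further motif.  These are
  confined to the *terminal restriction space*: states satisfying
  R(X) = AND over I in notDelta of (sigma_I(X) & F_I(X) &
  AND_{J in LDOI(I)} sigma_J(X)), where Delta collects all single-node motif
  drivers, minus states inside motif trap spaces and states inside
  self-negating stable motifs of the time-reversed system.

When a budget is exceeded the result degrades to bounds: the number of
maximal stable modules from below, the deletion-projection attractor count
from above.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .expanded import (
    ParityExpandedNetwork,
    VirtualNode,
    build_parity_expanded_network,
    is_consistent,
    parity_image,
)
from .expressions import ArityError, BoolFunc
from .motifs import (
    MotifSearchResult,
    TimeBudgetExceeded,
    _percolate,
    compute_ldoi,
    find_stable_motifs,
    single_node_drivers,
)
from .reduction import deletion_project
from .stg import Attractor, attractors_in_space, brute_force_attractors
from .system import BooleanSystem
from .transforms import time_reverse

__all__ = [
    "Budget",
    "TerminalRestrictionSpace",
    "SuccessionDiagram",
    "AttractorReport",
    "build_succession_diagram",
    "terminal_restriction_space",
    "find_motif_avoidant_attractors",
    "enumerate_attractors",
]


@dataclass(frozen=True)
class Budget:
    """Resource caps; exceeding any of them degrades results to bounds.

    ``time_limit`` (seconds, wall clock) is the stand-in criterion for an
    unusually computationally difficult network; None disables it.
    """

    motif_branches: int = 200_000
    space_bits: int = 18  # enumerate at most 2**space_bits states at a time
    succession_nodes: int = 4096
    time_limit: float | None = None

    def space_ok(self, nbits: int) -> bool:
        return nbits <= self.space_bits

    def deadline(self) -> float | None:
        return None if self.time_limit is None else time.monotonic() + self.time_limit


@dataclass(frozen=True)
class TerminalRestrictionSpace:
    """States that may hold a motif-avoidant attractor (theorem-level filter).

    The enumeration is stored compactly: ``fixed`` holds the variable values
    forced by the negated driver set and its LDOIs, ``subsystem`` is the
    system restricted to the remaining free variables, and ``sub_states``
    are the admissible free-variable states.  ``escape`` marks sub-states in
    which some pinned variable wants to flip (an outgoing transition that
    leaves the subspace, disqualifying any component through it).
    """

    system: BooleanSystem
    predicate: BoolFunc | None  # symbolic R, None when arity-blocked
    trivially_empty: bool  # notDelta inconsistent or self-negating => R == 0
    complete: bool
    fixed: tuple[tuple[str, int], ...] = ()
    subsystem: BooleanSystem | None = None
    sub_states: np.ndarray | None = None  # None when budget exceeded
    escape: np.ndarray | None = None

    def size(self) -> int | None:
        if self.trivially_empty:
            return 0
        return None if self.sub_states is None else int(self.sub_states.size)

    @property
    def states(self) -> "list[int] | None":
        """Enumerated states of the owning system (arbitrary width)."""
        if self.trivially_empty:
            return []
        if self.sub_states is None:
            return None
        fixed = dict(self.fixed)
        base = sum(1 << self.system.index(v) for v, s in fixed.items() if s)
        if self.subsystem is None:
            return [base] if self.sub_states.size else []
        pos = [self.system.index(v) for v in self.subsystem.variables]
        return sorted(
            base | sum(((int(s) >> j) & 1) << p for j, p in enumerate(pos))
            for s in self.sub_states
        )


def _sigma_func(node: VirtualNode) -> BoolFunc:
    f = BoolFunc.variable(node[0])
    return f if node[1] == 1 else f.negate()


def terminal_restriction_space(
    sys: BooleanSystem,
    pen: ParityExpandedNetwork | None = None,
    motifs: MotifSearchResult | None = None,
    budget: Budget = Budget(),
    deadline: float | None = None,
) -> TerminalRestrictionSpace:
    """Symbolic predicate R plus (when enumerable) the state list.

    R == 0 when notDelta contains a contradictory pair or is self-negating
    (every attractor then activates some motif); R == 1 when Delta is empty.
    The enumerated space further excludes states inside stable-motif trap
    spaces and states inside self-negating stable motifs of the time
    reversal.
    """
    pen = pen or build_parity_expanded_network(sys)
    if motifs is None:
        motifs = find_stable_motifs(pen, budget.motif_branches, deadline)
    try:
        delta = single_node_drivers(pen, motifs, deadline)
    except TimeBudgetExceeded:
        return TerminalRestrictionSpace(sys, None, False, False)
    not_delta = parity_image(delta)

    zero = TerminalRestrictionSpace(sys, BoolFunc.constant(0), True, True)
    if delta and not is_consistent(not_delta):
        return zero

    fixed: dict[str, int] = {}
    constraints: list[BoolFunc] = []
    predicate: BoolFunc | None = BoolFunc.constant(1)
    if not delta and not budget.space_ok(sys.n):
        return TerminalRestrictionSpace(sys, predicate, False, False)
    if delta:
        ldoi_union: set[VirtualNode] = set(not_delta)
        for node in sorted(not_delta):
            res = compute_ldoi(pen, {node})
            if res.self_negating:
                return zero
            ldoi_union |= res.ldoi
            constraints.append(pen.update_function(node))
        if not is_consistent(ldoi_union):
            return zero
        fixed = {n: s for n, s in ldoi_union}
        if not budget.space_ok(sys.n - len(fixed)):
            return TerminalRestrictionSpace(sys, None, False, False)
        try:
            for node in sorted(ldoi_union):
                predicate = predicate.and_(_sigma_func(node))
            for c in constraints:
                predicate = predicate.and_(c)
        except ArityError:
            predicate = None

    if deadline is not None and time.monotonic() > deadline:
        return TerminalRestrictionSpace(sys, predicate, False, False)
    # exclusions: forward motif trap spaces; self-negating reverse motifs
    excluded: list[dict[str, int]] = [m.as_assignment() for m in motifs]
    rev_pen = build_parity_expanded_network(time_reverse(sys))
    for m in find_stable_motifs(rev_pen, budget.motif_branches, deadline):
        if compute_ldoi(pen, m.nodes).self_negating:
            excluded.append(m.as_assignment())

    # enumerate compactly over the free variables only
    sub = sys.restricted(fixed) if fixed else sys
    if sub is None:  # every variable pinned: the space is a single state
        m = 1
        states = np.zeros(1, dtype=np.int64)
        keep = np.ones(1, dtype=bool)
        escape = np.zeros(1, dtype=bool)
        for v, s in fixed.items():
            g = sys.functions[v].restrict(fixed)
            escape[0] |= g.table & 1 != s
        return TerminalRestrictionSpace(
            sys, predicate, False, True, tuple(sorted(fixed.items())),
            None, states[keep], escape[keep],
        )
    m = 1 << sub.n
    states = np.arange(m, dtype=np.int64)
    keep = np.ones(m, dtype=bool)

    def eval_on_sub(f: BoolFunc) -> np.ndarray:
        g = f.restrict(fixed) if fixed else f
        pos = np.array([sub.index(u) for u in g.inputs], dtype=np.int64)
        idx = np.zeros(m, dtype=np.int64)
        for j, p in enumerate(pos):
            idx |= ((states >> p) & 1) << j
        return g.table_array()[idx].astype(bool)

    for c in constraints:
        keep &= eval_on_sub(c)
    for assignment in excluded:
        if any(fixed.get(v, s) != s for v, s in assignment.items() if v in fixed):
            continue  # the exclusion subspace misses the fixed slice entirely
        inside = np.ones(m, dtype=bool)
        for v, s in assignment.items():
            if v not in fixed:
                inside &= ((states >> sub.index(v)) & 1) == s
        keep &= ~inside
    escape = np.zeros(m, dtype=bool)
    for v, s in fixed.items():
        escape |= eval_on_sub(sys.functions[v]) != bool(s)
    return TerminalRestrictionSpace(
        sys, predicate, False, True, tuple(sorted(fixed.items())),
        sub, states[keep], escape[keep],
    )


def find_motif_avoidant_attractors(
    sys: BooleanSystem,
    space: TerminalRestrictionSpace,
    motifs: "MotifSearchResult | None" = None,
) -> list[Attractor]:
    """Terminal SCCs of the dynamics confined to the restriction space."""
    if space.trivially_empty or space.sub_states is None or space.sub_states.size == 0:
        return []
    fixed = dict(space.fixed)
    if space.subsystem is None:
        # single pinned state; an attractor iff nothing wants to flip
        if bool(space.escape[0]):
            return []
        state = sum(1 << sys.index(v) for v, s in fixed.items() if s)
        return [Attractor(sys, frozenset([state]))]
    sub_atts = attractors_in_space(space.subsystem, space.sub_states, space.escape)
    base = sum(1 << sys.index(v) for v, s in fixed.items() if s)
    pos = [sys.index(v) for v in space.subsystem.variables]
    atts = []
    for a in sub_atts:
        states = frozenset(
            base | sum(((s >> j) & 1) << p for j, p in enumerate(pos))
            for s in a.states
        )
        atts.append(Attractor(sys, states))
    if motifs:
        motif_sets = [m.nodes for m in motifs]

        def activates_motif(a: Attractor) -> bool:
            afix = a.fixed_variables()
            return any(all(afix.get(n) == s for n, s in ms) for ms in motif_sets)

        atts = [a for a in atts if not activates_motif(a)]
    return atts


def _projection_complex_analysis(
    residual: BooleanSystem, motifs: MotifSearchResult, budget: Budget
) -> tuple[list[Attractor] | None, int]:
    """Fallback when the restriction space cannot be enumerated.

    Returns (motif-avoidant attractors or None, count of unresolved complex
    attractors).  Point attractors survive deletion projection bijectively
    and complex attractors map onto at least one projected complex
    attractor, so:

    * a projection with no complex attractors proves the residual has no
      complex attractor, hence no motif-avoidant attractor;
    * a motif-free residual has no fixed points (every fixed point contains
      a stable motif), so all its attractors are complex; with exactly one
      projected complex attractor the residual has exactly one attractor,
      even though its states are not enumerated.
    """
    if not motifs.complete:
        return None, 0
    try:
        pm, projected = deletion_project(
            residual, max_arity=min(14, budget.space_bits), deadline=budget.deadline()
        )
    except ArityError:
        return None, 0
    if pm.blocked or not budget.space_ok(projected.n):
        return None, 0
    proj_atts = brute_force_attractors(projected)
    cplx = [a for a in proj_atts if not a.is_point]
    if not cplx:
        return [], 0
    if len(motifs) == 0:
        if len(proj_atts) == 1 and len(cplx) == 1:
            return [], 1
        return None, 0
    # Terminality via projection: stable-motif activity is preserved by the
    # deletion projection, so an original motif-avoidant attractor would
    # project onto a complex attractor fixing no motif's surviving literals.
    # If every projected complex attractor fully fixes some motif's surviving
    # literals, all of them stem from motif-activating attractors, which the
    # deeper succession branches enumerate.
    pv = set(projected.variables)
    surviving = []
    for m in motifs:
        surv = {(v, s) for v, s in m.nodes if v in pv}
        if not surv:
            return None, 0  # motif fully projected away: cannot classify
        surviving.append(surv)
    for a in cplx:
        afix = a.fixed_variables()
        if not any(all(afix.get(v) == s for v, s in sa) for sa in surviving):
            return None, 0  # potential motif-avoidant image: inconclusive
    return [], 0


@dataclass
class _SDNode:
    key: frozenset[VirtualNode]  # union of committed motif vertex sets
    fixed: dict[str, int]  # committed nodes plus their LDOI
    residual: BooleanSystem | None
    motifs: MotifSearchResult | None = None
    attractors: list[Attractor] = field(default_factory=list)  # full-system states
    motif_avoidant: list[Attractor] = field(default_factory=list)
    trs: TerminalRestrictionSpace | None = None
    complete: bool = True  # the attractor COUNT at this node is certain
    # complex attractors whose existence is proven via deletion projection but
    # whose member states were not enumerated
    unresolved: int = 0


@dataclass
class SuccessionDiagram:
    system: BooleanSystem
    graph: nx.DiGraph  # nodes are frozenset keys; edge attr "motif"
    nodes: dict[frozenset, _SDNode]
    complete: bool

    @property
    def root(self) -> frozenset:
        return frozenset()

    def leaves(self) -> list[frozenset]:
        return [k for k in self.graph.nodes if self.graph.out_degree(k) == 0]

    def all_attractors(self) -> list[Attractor]:
        seen: dict[frozenset, Attractor] = {}
        for node in self.nodes.values():
            for a in node.attractors + node.motif_avoidant:
                seen.setdefault(a.states, a)
        return sorted(seen.values(), key=lambda a: (len(a.states), min(a.states)))

    def n_unresolved(self) -> int:
        """Complex attractors proven to exist but not state-enumerated.

        Unresolved attractors live in pairwise distinct trap spaces (their
        nodes have distinct fixed sets), so they are counted without overlap
        with each other or with the state-enumerated attractors.
        """
        seen_fixed: set[frozenset] = set()
        total = 0
        for node in self.nodes.values():
            if node.unresolved:
                key = frozenset(node.fixed.items())
                if key not in seen_fixed:
                    seen_fixed.add(key)
                    total += node.unresolved
        return total

    def provenance(self) -> dict[frozenset, list[Attractor]]:
        out = {}
        for key, node in self.nodes.items():
            atts = node.attractors + node.motif_avoidant
            if atts:
                out[key] = atts
        return out

    def to_dot(self) -> str:
        def label(key):
            if not key:
                return "root"
            return ", ".join(f"{n}={s}" for n, s in sorted(key))

        lines = ["digraph SuccessionDiagram {"]
        for key in self.graph.nodes:
            natt = len(self.nodes[key].attractors) + len(self.nodes[key].motif_avoidant)
            suffix = f"\\n{natt} attractor(s)" if natt else ""
            lines.append(f'  "{label(key)}" [label="{label(key)}{suffix}"];')
        for u, v, data in self.graph.edges(data=True):
            motif = ", ".join(f"{n}={s}" for n, s in sorted(data.get("motif", ())))
            lines.append(f'  "{label(u)}" -> "{label(v)}" [label="{motif}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def _lift_attractors(
    sys: BooleanSystem, fixed: dict[str, int], residual: BooleanSystem, atts: list[Attractor]
) -> list[Attractor]:
    base = sum(1 << sys.index(v) for v, s in fixed.items() if s)
    pos = [sys.index(v) for v in residual.variables]
    out = []
    for a in atts:
        states = frozenset(
            base | sum(((s >> j) & 1) << p for j, p in enumerate(pos))
            for s in a.states
        )
        out.append(Attractor(sys, states))
    return out


def build_succession_diagram(sys: BooleanSystem, budget: Budget = Budget()) -> SuccessionDiagram:
    """Explore all stable-motif commitment orders, deduplicated by commitment."""
    graph = nx.DiGraph()
    nodes: dict[frozenset, _SDNode] = {}
    complete = True
    deadline = budget.deadline()
    # nodes whose commitments percolate to the same fixed set share their
    # residual analysis (motifs, restriction space, motif-avoidant search)
    analysis_cache: dict[frozenset, tuple] = {}

    def closure(committed: frozenset) -> dict[str, int]:
        pinned = {n: s for n, s in committed}
        driven, _ = _percolate(sys, pinned)
        fixed = dict(pinned)
        for n, s in driven:
            fixed.setdefault(n, s)
        return fixed

    def analyze(fixed: dict[str, int], residual: BooleanSystem):
        cache_key = frozenset(fixed.items())
        hit = analysis_cache.get(cache_key)
        if hit is None:
            rpen = build_parity_expanded_network(residual)
            motifs = find_stable_motifs(rpen, budget.motif_branches, deadline)
            unresolved = 0
            trs = terminal_restriction_space(residual, rpen, motifs, budget, deadline)
            if trs.complete:
                maas = find_motif_avoidant_attractors(residual, trs, motifs)
            else:
                maas, unresolved = _projection_complex_analysis(
                    residual, motifs, budget
                )
            hit = (motifs, trs, maas, unresolved)
            analysis_cache[cache_key] = hit
        return hit

    def explore(key: frozenset):
        nonlocal complete
        if key in nodes:
            return
        if len(nodes) >= budget.succession_nodes or (
            deadline is not None and time.monotonic() > deadline
        ):
            complete = False
            return
        fixed = closure(key)
        residual = sys.restricted(fixed) if fixed else sys
        node = _SDNode(key, fixed, residual)
        nodes[key] = node
        graph.add_node(key)
        if residual is None:
            state = sum(1 << sys.index(v) for v, s in fixed.items() if s)
            node.attractors = [Attractor(sys, frozenset([state]))]
            return
        motifs, trs, maas, unresolved = analyze(fixed, residual)
        node.motifs = motifs
        node.trs = trs
        node.unresolved = unresolved
        if not motifs.complete:
            node.complete = False
            complete = False
        if maas is not None:
            node.motif_avoidant = _lift_attractors(sys, fixed, residual, maas)
        else:
            node.complete = False
            complete = False
        for m in motifs:
            child = key | m.nodes
            explore(child)
            if child in nodes:
                graph.add_edge(key, child, motif=tuple(sorted(m.nodes)))

    explore(frozenset())
    return SuccessionDiagram(sys, graph, nodes, complete)


@dataclass
class AttractorReport:
    """Exact attractor count/list, or bounds when a budget was exceeded.

    ``exact`` means the attractor COUNT is certain.  ``attractors`` holds the
    state-enumerated attractors; ``unresolved`` counts complex attractors
    whose existence and uniqueness in their trap space is proven through
    deletion projection but whose member states were not enumerated.  When
    ``unresolved`` is zero and ``exact`` is set, the attractor list is the
    complete repertoire.
    """

    system: BooleanSystem
    attractors: list[Attractor] | None
    exact: bool
    lower: int
    upper: int | None
    unresolved: int = 0
    diagram: SuccessionDiagram | None = None
    flags: tuple[str, ...] = ()
    budget: Budget = Budget()

    @property
    def count(self) -> int | None:
        if not self.exact:
            return None
        return len(self.attractors) + self.unresolved

    @property
    def fully_resolved(self) -> bool:
        return self.exact and self.unresolved == 0

    def n_point(self) -> int | None:
        if self.attractors is None:
            return None
        return sum(1 for a in self.attractors if a.is_point)


def _projection_upper_bound(sys: BooleanSystem, budget: Budget) -> int | None:
    """Attractor count of the fully deletion-projected system.

    Point attractors are in bijection with the original's; complex attractors
    can only be more numerous, so the total is an upper bound.
    """
    try:
        pm, projected = deletion_project(
            sys, max_arity=min(14, budget.space_bits), deadline=budget.deadline()
        )
    except ArityError:
        return None
    if pm.blocked or not budget.space_ok(projected.n):
        return None
    return len(brute_force_attractors(projected))


def enumerate_attractors(sys: BooleanSystem, budget: Budget = Budget()) -> AttractorReport:
    """Full pipeline: succession diagram, motif-avoidant search, bounds fallback."""
    sd = build_succession_diagram(sys, budget)
    flags = []
    attractors = sd.all_attractors()
    unresolved = sd.n_unresolved()
    if sd.complete:
        total = len(attractors) + unresolved
        if unresolved:
            flags.append("complex-attractors-unresolved")
        return AttractorReport(
            sys, attractors, True, total, total, unresolved, sd, tuple(flags), budget
        )
    flags.append("succession-incomplete")
    # lower bound: distinct attractors actually established, at least 1
    lower = max(1, len(attractors) + unresolved)
    upper = _projection_upper_bound(sys, budget)
    if upper is None:
        flags.append("no-projection-upper-bound")
    elif upper < lower:  # only possible if the search itself was unsound
        flags.append("bound-inversion")
        upper = lower
    return AttractorReport(
        sys, None, False, lower, upper, unresolved, sd, tuple(flags), budget
    )
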