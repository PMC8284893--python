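"""Stable motifs, trap spaces, domains of influence, and Garden-of-Eden spaces.

A *stable module* is a non-empty, consistent, sourceless set of virtual
nodes: every member has at least one hyperedge whose parents all lie in the
set.  Its activity is self-sustaining, so it fixes a trap space.  A *stable
motif* is a minimal stable module (hence strongly connected).  Maximal
stable modules fix the minimal trap spaces; their count is a lower bound on
the attractor count.

The *logical domain of influence* LDOI(S) is the set of virtual nodes forced
by percolating the fixed values of S through the update functions.  It is a
computable subset of the full domain of influence DOI(S), which is defined
through the attractors of the S-pinned dynamics and is only evaluated here
by the brute-force oracle on small systems.  Percolation that forces a value
contradicting S is recorded as self-negation evidence: a self-negating set
cannot be held active in any attractor.

Stable motifs of the time-reversed system mark Garden-of-Eden spaces:
subspaces of the forward dynamics that no trajectory can enter.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import networkx as nx

from .expanded import (
    Hyperedge,
    ParityExpandedNetwork,
    VirtualNode,
    build_parity_expanded_network,
    is_consistent,
    parity_image,
)
from .stg import brute_force_attractors, garden_of_eden_states
from .system import BooleanSystem
from .transforms import time_reverse

__all__ = [
    "StableModule",
    "TrapSpace",
    "InfluenceResult",
    "MotifSearchResult",
    "compute_ldoi",
    "compute_doi_exact",
    "find_stable_motifs",
    "find_maximal_stable_modules",
    "exhaustive_stable_modules",
    "motif_trap_space",
    "single_node_drivers",
    "is_self_negating",
    "is_self_negating_exact",
    "garden_of_eden_spaces",
]

DEFAULT_MOTIF_BRANCHES = 200_000


class TimeBudgetExceeded(RuntimeError):
    """A wall-clock deadline was hit; partial results are not trustworthy."""


@dataclass(frozen=True)
class StableModule:
    network: ParityExpandedNetwork
    nodes: frozenset[VirtualNode]
    is_motif: bool = False

    def __post_init__(self):
        if not self.nodes:
            raise ValueError("stable modules are non-empty")
        if not is_consistent(self.nodes):
            raise ValueError("stable modules are consistent")

    @property
    def entities(self) -> frozenset[str]:
        return frozenset(n for n, _ in self.nodes)

    def as_assignment(self) -> dict[str, int]:
        return {n: s for n, s in self.nodes}


@dataclass(frozen=True)
class TrapSpace:
    """A partial state closed under the asynchronous dynamics."""

    fixed: tuple[tuple[str, int], ...]
    generators: frozenset[VirtualNode]

    @staticmethod
    def from_assignment(assignment: dict[str, int], generators=frozenset()) -> "TrapSpace":
        return TrapSpace(tuple(sorted(assignment.items())), frozenset(generators))

    def as_dict(self) -> dict[str, int]:
        return dict(self.fixed)

    def contains_state(self, sys: BooleanSystem, state: int) -> bool:
        return all((state >> sys.index(v)) & 1 == s for v, s in self.fixed)


@dataclass(frozen=True)
class InfluenceResult:
    sources: frozenset[VirtualNode]
    ldoi: frozenset[VirtualNode]
    self_negating: bool
    contradictions: tuple[VirtualNode, ...] = ()
    method: str = "ldoi"
    doi: frozenset[VirtualNode] | None = None


@dataclass(frozen=True)
class MotifSearchResult:
    motifs: tuple[StableModule, ...]
    complete: bool = True

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self):
        return len(self.motifs)


# ---------------------------------------------------------------------------
# Percolation / LDOI
# ---------------------------------------------------------------------------

def _perc_ctx(sys: BooleanSystem):
    """Cached per-system percolation context: dependents map + constant vars."""
    ctx = sys.__dict__.get("_perc_ctx")
    if ctx is None:
        dependents: dict[str, set[str]] = {}
        const_vars = []
        for v in sys.variables:
            f = sys.functions[v]
            if f.constant_value() is not None:
                const_vars.append(v)
            for u in f.inputs:
                dependents.setdefault(u, set()).add(v)
        ctx = (dependents, tuple(const_vars))
        object.__setattr__(sys, "_perc_ctx", ctx)
    return ctx


def _percolate(sys: BooleanSystem, pinned: dict[str, int]):
    """Iteratively fix values forced by ``pinned`` (which stays overriding).

    Returns (driven virtual nodes, contradiction witnesses): a pinned member
    whose own update function percolates to the opposite value is recorded as
    a contradiction and never added to the driven set.  Only the downstream
    cone of the pinned/constant variables is visited.
    """
    dependents, const_vars = _perc_ctx(sys)
    env = dict(pinned)
    funcs: dict[str, "object"] = {}
    driven: set[VirtualNode] = set()
    contradictions: list[VirtualNode] = []
    settled: set[str] = set()
    work = set(const_vars)
    for v in pinned:
        work.add(v)
        work |= dependents.get(v, set())
    while work:
        v = work.pop()
        if v in settled:
            continue
        f = funcs.get(v)
        if f is None:
            f = sys.functions[v]
        relevant = {u: env[u] for u in f.inputs if u in env}
        if relevant:
            f = f.restrict_fast(relevant)
            funcs[v] = f
        c = f.constant_value()
        if c is None:
            continue
        settled.add(v)
        if v in pinned:
            if pinned[v] == c:
                driven.add((v, c))
            else:
                contradictions.append((v, c))
        else:
            driven.add((v, c))
            env[v] = c
            work |= dependents.get(v, set()) - settled
    return frozenset(driven), tuple(contradictions)


def compute_ldoi(
    pen: ParityExpandedNetwork, S: "set[VirtualNode] | frozenset[VirtualNode]"
) -> InfluenceResult:
    """LDOI by iterated percolation of the pinned set S."""
    S = frozenset(S)
    if not is_consistent(S):
        raise ValueError(f"inconsistent source set {sorted(S)}")
    pinned = {n: s for n, s in S}
    driven, contradictions = _percolate(pen.system, pinned)
    return InfluenceResult(
        sources=S,
        ldoi=driven,
        self_negating=bool(contradictions),
        contradictions=contradictions,
        method="ldoi",
    )


def compute_doi_exact(
    sys: BooleanSystem,
    S: "set[VirtualNode] | frozenset[VirtualNode]",
    state_budget: int = 1 << 16,
) -> InfluenceResult:
    """Exact DOI through the attractors of the S-pinned dynamics (oracle scale).

    A virtual node (j, s) consistent with S is driven when F_(j,s) = 1 on
    every attractor state of the dynamics restricted to the subspace where S
    is active.  Also records contradiction evidence for pinned members whose
    update function is the opposite constant on all attractor states.
    """
    S = frozenset(S)
    if not is_consistent(S):
        raise ValueError(f"inconsistent source set {sorted(S)}")
    pinned = {n: s for n, s in S}
    residual = sys.restricted(pinned)
    if residual is None:
        attractor_envs = [dict(pinned)]
    else:
        if (1 << residual.n) > state_budget:
            raise RuntimeError("state budget exceeded for exact DOI")
        attractor_envs = []
        for att in brute_force_attractors(residual):
            for state in att.states:
                env = residual.state_env(state)
                env.update(pinned)
                attractor_envs.append(env)
    doi: set[VirtualNode] = set()
    contradictions: list[VirtualNode] = []
    for j in sys.variables:
        f = sys.functions[j]
        vals = {f(env) for env in attractor_envs}
        if len(vals) != 1:
            continue
        val = vals.pop()
        if j in pinned and pinned[j] != val:
            contradictions.append((j, val))
        else:
            doi.add((j, val))
    ldoi = compute_ldoi(build_parity_expanded_network(sys), S)
    return InfluenceResult(
        sources=S,
        ldoi=ldoi.ldoi,
        self_negating=bool(contradictions),
        contradictions=tuple(contradictions),
        method="doi",
        doi=frozenset(doi),
    )


# ---------------------------------------------------------------------------
# Stable motif enumeration
# ---------------------------------------------------------------------------

def _feedback_entities(sys: BooleanSystem) -> set[str]:
    """Entities on a cycle of the interaction digraph (incl. self-loops)."""
    g = nx.DiGraph()
    g.add_nodes_from(sys.variables)
    for v in sys.variables:
        for u in sys.functions[v].inputs:
            g.add_edge(u, v)
    core = set()
    for scc in nx.strongly_connected_components(g):
        if len(scc) > 1:
            core |= scc
        else:
            (v,) = scc
            if g.has_edge(v, v):
                core.add(v)
    return core


def find_stable_motifs(
    pen: ParityExpandedNetwork,
    max_branches: int = DEFAULT_MOTIF_BRANCHES,
    deadline: float | None = None,
) -> MotifSearchResult:
    """All stable motifs (minimal stable modules) of the network.

    Search strategy: every motif is the closure of any of its members under a
    choice of one supporting hyperedge per member, so a depth-first search
    over hyperedge choices from each virtual node enumerates all motifs.
    Branches whose committed set already contains a known module cannot yield
    a minimal module and are pruned.  A branch budget caps combinatorial
    explosion; exceeding it flags the result incomplete instead of failing.
    """
    sys = pen.system
    found: list[frozenset[VirtualNode]] = []
    # constant update functions induce singleton motifs via tautology edges
    const_entities = set()
    for v in sys.variables:
        c = sys.functions[v].constant_value()
        if c is not None:
            found.append(frozenset([(v, c)]))
            const_entities.add(v)
    allowed = _feedback_entities(sys) | const_entities
    edges_into: dict[VirtualNode, list[Hyperedge]] = {}
    for v in allowed:
        for s in (1, 0):
            edges_into[(v, s)] = [
                e
                for e in pen.edges_into((v, s))
                if all(p[0] in allowed for p in e.parents)
            ]
    branches = 0
    complete = True
    for start in sorted(edges_into):
        stack: list[tuple[frozenset, tuple]] = [(frozenset([start]), (start,))]
        while stack:
            S, todo = stack.pop()
            if any(S >= R for R in found):
                continue
            if not todo:
                found.append(S)
                continue
            branches += 1
            if branches > max_branches or (
                deadline is not None
                and branches % 512 == 0
                and time.monotonic() > deadline
            ):
                complete = False
                stack.clear()
                break
            J, rest = todo[0], todo[1:]
            contra = parity_image(S)
            for e in edges_into.get(J, []):
                if e.parents & contra:
                    continue
                new = e.parents - S
                stack.append((S | new, rest + tuple(sorted(new))))
        if not complete:
            break
    minimal = [
        m for m in found if not any(other < m for other in found)
    ]
    minimal = sorted(set(minimal), key=lambda m: sorted(m))
    motifs = tuple(StableModule(pen, m, is_motif=True) for m in minimal)
    return MotifSearchResult(motifs, complete)


def exhaustive_stable_modules(pen: ParityExpandedNetwork) -> tuple[list[frozenset], list[frozenset]]:
    """(all stable modules, maximal stable modules) by brute-force subset scan.

    Test oracle; exponential in the number of entities.
    """
    from itertools import product

    sys = pen.system
    modules = []
    for values in product((None, 0, 1), repeat=sys.n):
        nodes = frozenset(
            (sys.variables[i], v) for i, v in enumerate(values) if v is not None
        )
        if not nodes:
            continue
        if all(
            any(e.parents <= nodes for e in pen.edges_into(node)) for node in nodes
        ):
            modules.append(nodes)
    maximal = [m for m in modules if not any(m < other for other in modules)]
    return modules, maximal


def find_maximal_stable_modules(
    sys_or_pen, max_branches: int = DEFAULT_MOTIF_BRANCHES
) -> MotifSearchResult:
    """Maximal stable modules = fixed virtual-node sets of the commitment leaves.

    Obtained by recursively committing stable motifs and percolating until no
    motif remains; the deduplicated leaf fixed-sets are the maximal modules
    and fix the system's minimal trap spaces (pairwise disjoint subspaces).
    """
    pen = (
        sys_or_pen
        if isinstance(sys_or_pen, ParityExpandedNetwork)
        else build_parity_expanded_network(sys_or_pen)
    )
    sys = pen.system
    leaves: set[frozenset[VirtualNode]] = set()
    complete = True
    seen: set[frozenset] = set()

    def rec(fixed: dict[str, int]):
        nonlocal complete
        key = frozenset(fixed.items())
        if key in seen:
            return
        seen.add(key)
        residual = sys.restricted(fixed) if fixed else sys
        if residual is None:
            leaves.add(frozenset((v, s) for v, s in fixed.items()))
            return
        rpen = build_parity_expanded_network(residual)
        res = find_stable_motifs(rpen, max_branches)
        if not res.complete:
            complete = False
        if not res.motifs:
            leaves.add(frozenset((v, s) for v, s in fixed.items()))
            return
        for m in res.motifs:
            pinned = dict(fixed)
            pinned.update(m.as_assignment())
            driven, _ = _percolate(sys, pinned)
            new_fixed = dict(pinned)
            for n, s in driven:
                new_fixed.setdefault(n, s)
            rec(new_fixed)

    driven0, _ = _percolate(sys, {})
    rec({n: s for n, s in driven0})
    leaves.discard(frozenset())
    mods = sorted(leaves, key=lambda m: sorted(m))
    return MotifSearchResult(
        tuple(StableModule(pen, m, is_motif=False) for m in mods), complete
    )


# ---------------------------------------------------------------------------
# Trap spaces, drivers, self-negation, Gardens of Eden
# ---------------------------------------------------------------------------

def motif_trap_space(M: StableModule) -> TrapSpace:
    """The partial state fixed by a stable module's activity."""
    return TrapSpace.from_assignment(M.as_assignment(), M.nodes)


def single_node_drivers(
    pen: ParityExpandedNetwork,
    motifs: "MotifSearchResult | list[StableModule]",
    deadline: float | None = None,
) -> set[VirtualNode]:
    """Delta: virtual nodes whose LDOI contains some stable motif's vertex set.

    Raises TimeBudgetExceeded past the deadline: a partial Delta would make
    the terminal-restriction predicate unsound, so none is returned.
    """
    motif_sets = [m.nodes for m in motifs]
    delta = set()
    for i, node in enumerate(pen.virtual_nodes):
        if deadline is not None and i % 16 == 0 and time.monotonic() > deadline:
            raise TimeBudgetExceeded("driver scan timed out")
        ldoi = compute_ldoi(pen, {node}).ldoi
        if any(ms <= ldoi for ms in motif_sets):
            delta.add(node)
    return delta


def is_self_negating(
    pen: ParityExpandedNetwork, S: "set[VirtualNode] | frozenset[VirtualNode]"
) -> tuple[bool, tuple[VirtualNode, ...]]:
    """Conservative self-negation test via LDOI percolation.

    Sound but incomplete: a True verdict is definitive (S cannot stay active
    in any attractor); a False verdict may be refuted by the exact DOI test.
    """
    res = compute_ldoi(pen, S)
    return res.self_negating, res.contradictions


def is_self_negating_exact(
    sys: BooleanSystem,
    S: "set[VirtualNode] | frozenset[VirtualNode]",
    max_subset: int = 12,
) -> bool:
    """Definition-level test: some subset T of DOI(S) - S drives a node
    contradicting S.  Oracle scale only (exponential in |DOI(S) - S|)."""
    from itertools import combinations

    S = frozenset(S)
    base = compute_doi_exact(sys, S)
    if base.self_negating:
        return True
    rest = sorted(base.doi - S)
    if len(rest) > max_subset:
        rest = rest[:max_subset]
    target = parity_image(S)
    for r in range(1, len(rest) + 1):
        for T in combinations(rest, r):
            res = compute_doi_exact(sys, frozenset(T))
            if (res.doi & target) or any(c in target for c in res.contradictions):
                return True
    return False


def garden_of_eden_spaces(
    sys: BooleanSystem,
    state_budget: int = 1 << 16,
    max_branches: int = DEFAULT_MOTIF_BRANCHES,
) -> tuple[list[TrapSpace], list[int] | None]:
    """Unstable subspaces (trap spaces of the time reversal) and, at oracle
    scale, the individual Garden-of-Eden states.

    A Garden-of-Eden state has no incoming change-edge and at least one
    outgoing one: an isolated fixed point persists forever (it reaches
    itself), so it does not qualify even though it is a source node of the
    self-loop-free STG.
    """
    rev = time_reverse(sys)
    rpen = build_parity_expanded_network(rev)
    spaces = [motif_trap_space(m) for m in find_stable_motifs(rpen, max_branches)]
    sources = None
    if (1 << sys.n) <= state_budget:
        sources = [
            s for s in garden_of_eden_states(sys) if not sys.is_fixed_point(s)
        ]
    return spaces, sources
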