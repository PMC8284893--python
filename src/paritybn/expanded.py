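"""The parity-expanded network: prime-implicant hypergraph on virtual nodes.

Each system entity i yields two *virtual nodes*, the ordered pairs (i, 1)
and (i, 0) — a contradictory pair.  A set of virtual nodes containing no
contradictory pair is *consistent*.  Virtual node (i, 1) updates by
F_(i,1) = f_i and lives in the original-update layer; (i, 0) updates by
F_(i,0) = !f_i and lives in the parity-update layer.  A hyperedge connects a
parent set S to a child J when the conjunction of the parents' indicator
literals is a prime implicant of F_J.  Hyperedges with two or more parents
are rendered through intermediary composite nodes (AND gates); network
equality is defined on hyperedges, composite identifiers are cosmetic.

The network is invariant under parity of the underlying system up to the
relabeling (i, s) -> (i, !s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .expressions import BoolFunc
from .primes import prime_implicants_of_func
from .system import BooleanSystem

VirtualNode = tuple[str, int]

__all__ = [
    "VirtualNode",
    "Hyperedge",
    "ParityExpandedNetwork",
    "build_parity_expanded_network",
    "parity_image",
    "is_consistent",
]


def parity_image(S: "set[VirtualNode] | frozenset[VirtualNode]") -> set[VirtualNode]:
    """{(i, !s) : (i, s) in S}.  S is consistent iff disjoint from its image."""
    return {(name, 1 - val) for name, val in S}


def is_consistent(S) -> bool:
    return not (set(S) & parity_image(S))


@dataclass(frozen=True)
class Hyperedge:
    parents: frozenset[VirtualNode]
    child: VirtualNode
    composite: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if not is_consistent(self.parents):
            raise ValueError(f"inconsistent parent set {sorted(self.parents)}")


@dataclass(frozen=True)
class ParityExpandedNetwork:
    system: BooleanSystem
    hyperedges: tuple[Hyperedge, ...]

    @property
    def virtual_nodes(self) -> list[VirtualNode]:
        return [(v, s) for v in self.system.variables for s in (1, 0)]

    def layer(self, node: VirtualNode) -> str:
        return "original" if node[1] == 1 else "parity"

    def update_function(self, node: VirtualNode) -> BoolFunc:
        """F_I: f_i for (i,1), the negation of f_i for (i,0)."""
        f = self.system.functions[node[0]]
        return f if node[1] == 1 else f.negate()

    def edges_into(self, node: VirtualNode) -> list[Hyperedge]:
        return self._index().get(node, [])

    def _index(self) -> dict[VirtualNode, list[Hyperedge]]:
        cache = self.__dict__.get("_edge_index")
        if cache is None:
            cache = {}
            for e in self.hyperedges:
                cache.setdefault(e.child, []).append(e)
            object.__setattr__(self, "_edge_index", cache)
        return cache

    def composite_nodes(self) -> list[Hyperedge]:
        return [e for e in self.hyperedges if len(e.parents) >= 2]

    def edge_set(self) -> frozenset[tuple[frozenset[VirtualNode], VirtualNode]]:
        """Hyperedge structure used for network equality."""
        return frozenset((e.parents, e.child) for e in self.hyperedges)

    def relabeled_by_parity(self) -> frozenset:
        return frozenset(
            (frozenset((n, 1 - s) for n, s in parents), (child[0], 1 - child[1]))
            for parents, child in self.edge_set()
        )

    # -- graph views ------------------------------------------------------
    def to_digraph(self) -> nx.DiGraph:
        """Plain digraph with virtual nodes and composite AND-gate nodes."""
        g = nx.DiGraph()
        for node in self.virtual_nodes:
            g.add_node(node, kind="virtual")
        for e in self.hyperedges:
            if len(e.parents) >= 2:
                g.add_node(e.composite, kind="composite")
                for p in e.parents:
                    g.add_edge(p, e.composite)
                g.add_edge(e.composite, e.child)
            else:
                for p in e.parents:
                    g.add_edge(p, e.child)
        return g

    def to_dot(self, highlight: "set[VirtualNode] | None" = None) -> str:
        highlight = highlight or set()
        lines = ["digraph ParityExpandedNetwork {"]
        for name, val in self.virtual_nodes:
            style = ', style=filled, fillcolor="palegreen"' if (name, val) in highlight else ""
            lines.append(f'  "{name}={val}" [shape=ellipse{style}];')
        for e in self.hyperedges:
            if len(e.parents) >= 2:
                lines.append(f'  "{e.composite}" [shape=point, width=0.12, label=""];')
                for p in sorted(e.parents):
                    lines.append(f'  "{p[0]}={p[1]}" -> "{e.composite}";')
                lines.append(f'  "{e.composite}" -> "{e.child[0]}={e.child[1]}";')
            else:
                for p in sorted(e.parents):
                    lines.append(f'  "{p[0]}={p[1]}" -> "{e.child[0]}={e.child[1]}";')
        lines.append("}")
        return "\n".join(lines) + "\n"

    def to_graphml(self) -> str:
        g = self.to_digraph()
        g = nx.relabel_nodes(
            g,
            {n: (f"{n[0]}={n[1]}" if isinstance(n, tuple) else str(n)) for n in g.nodes},
        )
        return "\n".join(nx.generate_graphml(g))


def build_parity_expanded_network(sys: BooleanSystem) -> ParityExpandedNetwork:
    """Hyperedges from the complete prime implicant sets of every f_i and !f_i.

    Constant-1 update functions yield a single empty-parent hyperedge (the
    child is unconditionally driven); constant-0 functions yield none.
    """
    edges: list[Hyperedge] = []
    counter = 0
    for name in sys.variables:
        f = sys.functions[name]
        for val, func in ((1, f), (0, f.negate())):
            child = (name, val)
            for pi in prime_implicants_of_func(func):
                comp = None
                if len(pi) >= 2:
                    comp = f"AND_{counter}"
                    counter += 1
                edges.append(Hyperedge(frozenset(pi), child, comp))
    return ParityExpandedNetwork(sys, tuple(edges))
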