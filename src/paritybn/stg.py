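"""State transition graphs and the brute-force attractor oracle.

The STG of an N-variable system has 2^N states and a directed change-edge
x -> y whenever y differs from x in exactly one coordinate i and f_i(x)
equals the flipped value.  Self-loops (updates that change nothing) are not
stored; attractors, being terminal strongly connected components, are
unaffected.

Two code paths coexist: a networkx graph for inspection/export, and a
vectorized numpy + scipy.sparse.csgraph path used by the attractor searches,
which also works on an arbitrary subset of states (needed for the terminal
restriction space search).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.sparse import csgraph

from .system import BooleanSystem

__all__ = [
    "StateBudgetError",
    "Attractor",
    "build_stg",
    "terminal_sccs",
    "attractors_in_space",
    "brute_force_attractors",
    "garden_of_eden_states",
    "stg_to_dot",
    "stg_to_graphml",
]

DEFAULT_STATE_BUDGET = 1 << 22


class StateBudgetError(RuntimeError):
    """2^N exceeds the configured state budget; use symbolic/restricted paths."""


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the STG; ``point`` iff it has exactly one state."""

    system: BooleanSystem
    states: frozenset[int]

    @property
    def is_point(self) -> bool:
        return len(self.states) == 1

    def fixed_variables(self) -> dict[str, int]:
        """Variables holding the same value across all member states."""
        states = list(self.states)
        out = {}
        for i, v in enumerate(self.system.variables):
            vals = {(s >> i) & 1 for s in states}
            if len(vals) == 1:
                out[v] = vals.pop()
        return out

    def state_strings(self) -> list[str]:
        return sorted(self.system.state_to_str(s) for s in self.states)

    def __len__(self) -> int:
        return len(self.states)


def build_stg(sys: BooleanSystem, state_budget: int = DEFAULT_STATE_BUDGET) -> nx.DiGraph:
    """Full STG as a networkx DiGraph with integer state nodes."""
    if (1 << sys.n) > state_budget:
        raise StateBudgetError(
            f"2^{sys.n} states exceed the budget of {state_budget}"
        )
    g = nx.DiGraph(system=sys)
    states = np.arange(1 << sys.n, dtype=np.int64)
    g.add_nodes_from(int(s) for s in states)
    nv = sys.next_values(states)
    for i in range(sys.n):
        changed = np.nonzero(nv[:, i] != ((states >> i) & 1))[0]
        for s in changed:
            g.add_edge(int(states[s]), int(states[s] ^ (1 << i)))
    return g


def terminal_sccs(stg: nx.DiGraph) -> list[Attractor]:
    """Attractors = SCCs with no outgoing edges.  Ground-truth oracle."""
    sys = stg.graph["system"]
    cond = nx.condensation(stg)
    out = []
    for comp_id in cond.nodes:
        if cond.out_degree(comp_id) == 0:
            members = frozenset(cond.nodes[comp_id]["members"])
            out.append(Attractor(sys, members))
    out.sort(key=lambda a: min(a.states))
    return out


def _space_edges(sys: BooleanSystem, states: np.ndarray):
    """Change-edges among ``states`` plus a leaves-space flag per state."""
    m = states.size
    nv = sys.next_values(states)
    rows_l, cols_l = [], []
    out_flag = np.zeros(m, dtype=bool)
    for i in range(sys.n):
        changed = np.nonzero(nv[:, i] != ((states >> i) & 1))[0]
        if changed.size == 0:
            continue
        targets = states[changed] ^ (1 << i)
        pos = np.searchsorted(states, targets)
        pos = np.clip(pos, 0, m - 1)
        inside = states[pos] == targets
        rows_l.append(changed[inside])
        cols_l.append(pos[inside])
        out_flag[changed[~inside]] = True
    rows = np.concatenate(rows_l) if rows_l else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols_l) if cols_l else np.empty(0, dtype=np.int64)
    return rows, cols, out_flag


def attractors_in_space(
    sys: BooleanSystem, states: np.ndarray, escape: np.ndarray | None = None
) -> list[Attractor]:
    """Terminal SCCs of the full dynamics that lie entirely inside ``states``.

    A component counts only if no member state has any successor outside the
    component (inside or outside the supplied space), so the result is exact
    for any space known to confine the attractors of interest.  ``escape``
    optionally marks states with an additional outgoing transition not
    captured by this system's variables (used when the space lives inside a
    pinned subspace of a larger system).
    """
    states = np.asarray(states, dtype=np.int64)
    order = np.argsort(states)
    states = states[order]
    if escape is not None:
        escape = np.asarray(escape, dtype=bool)[order]
    if states.size == 0:
        return []
    rows, cols, out_flag = _space_edges(sys, states)
    if escape is not None:
        out_flag |= escape
    m = states.size
    adj = sparse.csr_matrix(
        (np.ones(rows.size, dtype=np.int8), (rows, cols)), shape=(m, m)
    )
    ncomp, labels = csgraph.connected_components(adj, directed=True, connection="strong")
    bad = np.zeros(ncomp, dtype=bool)
    bad[labels[out_flag]] = True
    cross = labels[rows] != labels[cols]
    bad[labels[rows[cross]]] = True
    out = []
    for comp_id in np.nonzero(~bad)[0]:
        members = frozenset(int(s) for s in states[labels == comp_id])
        out.append(Attractor(sys, members))
    out.sort(key=lambda a: min(a.states))
    return out


def brute_force_attractors(
    sys: BooleanSystem, state_budget: int = DEFAULT_STATE_BUDGET
) -> list[Attractor]:
    """Exact attractors by exhaustive state enumeration (oracle scale)."""
    if (1 << sys.n) > state_budget:
        raise StateBudgetError(
            f"2^{sys.n} states exceed the budget of {state_budget}"
        )
    return attractors_in_space(sys, np.arange(1 << sys.n, dtype=np.int64))


def garden_of_eden_states(sys: BooleanSystem, state_budget: int = DEFAULT_STATE_BUDGET) -> list[int]:
    """Source states of the STG (in-degree zero), by exhaustive enumeration."""
    if (1 << sys.n) > state_budget:
        raise StateBudgetError(
            f"2^{sys.n} states exceed the budget of {state_budget}"
        )
    states = np.arange(1 << sys.n, dtype=np.int64)
    nv = sys.next_values(states)
    has_in = np.zeros(states.size, dtype=bool)
    for i in range(sys.n):
        changed = np.nonzero(nv[:, i] != ((states >> i) & 1))[0]
        has_in[states[changed] ^ (1 << i)] = True
    return [int(s) for s in states[~has_in]]


# -- export -----------------------------------------------------------------

def _relabel(stg: nx.DiGraph) -> nx.DiGraph:
    sys = stg.graph["system"]
    g = nx.relabel_nodes(stg, {s: sys.state_to_str(s) for s in stg.nodes}, copy=True)
    g.graph.pop("system", None)
    return g


def stg_to_dot(stg: nx.DiGraph) -> str:
    g = _relabel(stg)
    lines = ["digraph STG {"]
    for node in sorted(g.nodes):
        lines.append(f'  "{node}";')
    for u, v in sorted(g.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def stg_to_graphml(stg: nx.DiGraph) -> str:
    g = _relabel(stg)
    return "\n".join(nx.generate_graphml(g))
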