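"""Network reduction: stable-motif commitment and deletion projection.

Committing a stable motif M restricts the dynamics to M's trap space: the
motif's variables and everything in its LDOI are fixed, the remaining update
functions are partially evaluated, and the attractors of the original system
inside the trap space correspond one-to-one to the attractors of the
residual system extended by the fixed values.

Deletion projection eliminates variables that do not self-regulate by
substituting their update functions into their successors'.  Point
attractors survive the projection exactly (through representative states);
every complex attractor of the original maps onto at least one complex
attractor of the projection, so projected complex-attractor counts are upper
bounds.  The induced projection map does not depend on the deletion order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .expanded import VirtualNode, build_parity_expanded_network
from .expressions import ArityError, BoolFunc
from .motifs import StableModule, _percolate
from .system import BooleanSystem

__all__ = ["ReducedSystem", "ProjectionMap", "reduce_by_motif", "deletion_project"]


@dataclass(frozen=True)
class ReducedSystem:
    parent: BooleanSystem
    fixed: tuple[tuple[str, int], ...]
    residual: BooleanSystem | None  # None when every variable is fixed

    def fixed_dict(self) -> dict[str, int]:
        return dict(self.fixed)

    def lift_state(self, residual_state: int | None = None) -> int:
        """Full-system state from fixed values plus a residual state."""
        state = 0
        fixed = self.fixed_dict()
        for i, v in enumerate(self.parent.variables):
            if v in fixed:
                if fixed[v]:
                    state |= 1 << i
            else:
                if residual_state is None:
                    raise ValueError("residual state required")
                j = self.residual.index(v)
                if (residual_state >> j) & 1:
                    state |= 1 << i
        return state


def _is_stable_module(sys: BooleanSystem, nodes: frozenset[VirtualNode]) -> bool:
    pen = build_parity_expanded_network(sys)
    return all(any(e.parents <= nodes for e in pen.edges_into(n)) for n in nodes)


def reduce_by_motif(
    sys: BooleanSystem, M: "StableModule | frozenset[VirtualNode]", validate: bool = True
) -> ReducedSystem:
    """Fix M and its LDOI; return the residual system on the unfixed variables."""
    nodes = M.nodes if isinstance(M, StableModule) else frozenset(M)
    if validate and not _is_stable_module(sys, nodes):
        raise ValueError(f"{sorted(nodes)} is not a stable module of the system")
    pinned = {n: s for n, s in nodes}
    driven, _ = _percolate(sys, pinned)
    fixed = dict(pinned)
    for n, s in driven:
        fixed.setdefault(n, s)
    residual = sys.restricted(fixed)
    return ReducedSystem(sys, tuple(sorted(fixed.items())), residual)


@dataclass(frozen=True)
class ProjectionMap:
    """Record of a deletion projection, with representative-state lifting."""

    parent: BooleanSystem
    projected: BooleanSystem
    deleted: tuple[str, ...]  # in deletion order
    definitions: dict[str, BoolFunc] = field(compare=False)
    blocked: tuple[str, ...] = ()  # non-self-regulating but arity-blocked

    def project_state(self, parent_state: int) -> int:
        out = 0
        for j, v in enumerate(self.projected.variables):
            if (parent_state >> self.parent.index(v)) & 1:
                out |= 1 << j
        return out

    def lift_state(self, projected_state: int) -> int:
        """Representative parent state: percolate the projected values through
        the deleted variables' definitions, most recently deleted first."""
        env = {
            v: (projected_state >> j) & 1
            for j, v in enumerate(self.projected.variables)
        }
        for v in reversed(self.deleted):
            env[v] = self.definitions[v](env)
        state = 0
        for i, v in enumerate(self.parent.variables):
            if env[v]:
                state |= 1 << i
        return state


def _self_regulating(funcs: dict[str, BoolFunc], v: str) -> bool:
    return v in funcs[v].inputs


def deletion_project(
    sys: BooleanSystem,
    targets: "list[str] | None" = None,
    max_arity: int | None = None,
    deadline: float | None = None,
) -> tuple[ProjectionMap, BooleanSystem]:
    """Delete non-self-regulating variables by substitution.

    With ``targets`` given, exactly those variables are deleted (error if one
    self-regulates when its turn comes); otherwise variables are deleted
    until every remaining one self-regulates, prioritizing variables whose
    update function is constant.  At least one variable is always kept.
    Deletions whose substitution would push some update function past
    ``max_arity`` inputs are skipped (the variable is reported as blocked).
    """
    import time as _time

    funcs = {v: sys.functions[v] for v in sys.variables}
    remaining = list(sys.variables)
    deleted: list[str] = []
    definitions: dict[str, BoolFunc] = {}
    blocked: set[str] = set()

    def pick() -> str | None:
        if targets is not None:
            want = [t for t in targets if t not in deleted]
            if not want:
                return None
            v = want[0]
            if v not in remaining:
                raise ValueError(f"unknown or already deleted variable {v!r}")
            if _self_regulating(funcs, v):
                raise ValueError(f"cannot delete self-regulating variable {v!r}")
            return v
        candidates = [
            v for v in remaining if not _self_regulating(funcs, v) and v not in blocked
        ]
        if not candidates or len(remaining) == 1:
            return None
        for v in candidates:  # constants first, then declaration order
            if funcs[v].is_constant():
                return v
        return candidates[0]

    while True:
        if deadline is not None and _time.monotonic() > deadline:
            blocked.update(
                w for w in remaining if not _self_regulating(funcs, w)
            )
            break
        v = pick()
        if v is None:
            break
        fv = funcs[v]
        if max_arity is not None:
            widest = max(
                (
                    len((set(funcs[w].inputs) | set(fv.inputs)) - {v})
                    for w in remaining
                    if w != v and v in funcs[w].inputs
                ),
                default=0,
            )
            if widest > max_arity:
                if targets is not None:
                    raise ArityError(f"deleting {v!r} exceeds arity cap {max_arity}")
                blocked.add(v)
                continue
        try:
            new_funcs = {
                w: (funcs[w].compose(v, fv) if v in funcs[w].inputs else funcs[w])
                for w in remaining
                if w != v
            }
        except ArityError:
            if targets is not None:
                raise
            blocked.add(v)
            continue
        funcs = new_funcs
        remaining.remove(v)
        deleted.append(v)
        definitions[v] = fv

    projected = BooleanSystem(tuple(remaining), dict(funcs))
    pm = ProjectionMap(sys, projected, tuple(deleted), definitions, tuple(sorted(blocked)))
    return pm, projected
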