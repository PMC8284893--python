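"""Boolean systems under stochastic asynchronous update, and BoolNet-style I/O.

A *system* is an ordered list of N named variables together with one update
function per variable.  The update scheme is implicit and stochastic
asynchronous: at each step a single randomly chosen variable recomputes its
value.  Because the topology of the state transition graph does not depend on
the update probabilities, no probabilities are stored.

States are integers: bit i holds the value of ``variables[i]``.  The printable
form puts the first declared variable leftmost, so a three-variable system
over A, B, C prints states as the triple X_A X_B X_C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expressions import (
    BoolFunc,
    ExpressionSyntaxError,
    expr_to_str,
    expr_variables,
    parse_expression,
)

__all__ = [
    "BooleanSystem",
    "BnetError",
    "parse_bnet",
    "write_bnet",
    "asynchronous_successors",
]


class BnetError(ValueError):
    """Malformed rule file; carries the offending line number (1-based)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class BooleanSystem:
    """N update functions over named variables, asynchronously updated."""

    variables: tuple[str, ...]
    functions: dict[str, BoolFunc]
    source_exprs: dict[str, tuple] = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        if len(self.variables) < 1:
            raise ValueError("a system needs at least one variable")
        if set(self.variables) != set(self.functions):
            raise ValueError("every variable needs exactly one update function")
        declared = set(self.variables)
        for name, f in self.functions.items():
            missing = set(f.inputs) - declared
            if missing:
                raise ValueError(
                    f"update function of {name} references unknown variable(s) "
                    f"{sorted(missing)}"
                )

    # -- basic structure --------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        return self.variables.index(name)

    def function(self, name: str) -> BoolFunc:
        return self.functions[name]

    # -- states -----------------------------------------------------------
    def state_to_str(self, state: int) -> str:
        return "".join(str((state >> i) & 1) for i in range(self.n))

    def str_to_state(self, s: str) -> int:
        if len(s) != self.n:
            raise ValueError(f"state string must have length {self.n}")
        return sum(1 << i for i, c in enumerate(s) if c == "1")

    def state_env(self, state: int) -> dict[str, int]:
        return {v: (state >> i) & 1 for i, v in enumerate(self.variables)}

    def evaluate(self, name: str, state: int) -> int:
        return self.functions[name](self.state_env(state))

    # -- vectorized evaluation --------------------------------------------
    def _fast_tables(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per variable: (input bit positions, table array)."""
        idx = {v: i for i, v in enumerate(self.variables)}
        out = []
        for v in self.variables:
            f = self.functions[v]
            pos = np.array([idx[u] for u in f.inputs], dtype=np.int64)
            out.append((pos, f.table_array()))
        return out

    def next_values(self, states: np.ndarray) -> np.ndarray:
        """f_i applied to each state; shape (len(states), N) uint8 array."""
        states = np.asarray(states, dtype=np.int64)
        out = np.empty((states.size, self.n), dtype=np.uint8)
        for i, (pos, table) in enumerate(self._fast_tables()):
            if pos.size == 0:
                out[:, i] = table[0]
            else:
                sub = np.zeros(states.size, dtype=np.int64)
                for j, p in enumerate(pos):
                    sub |= ((states >> p) & 1) << j
                out[:, i] = table[sub]
        return out

    # -- dynamics ----------------------------------------------------------
    def successors(self, state: int) -> set[int]:
        """Asynchronous successors: one-variable updates that change the state."""
        if state < 0 or state >> self.n:
            raise ValueError("state out of range for this system")
        env = self.state_env(state)
        out = set()
        for i, v in enumerate(self.variables):
            if self.functions[v](env) != (state >> i) & 1:
                out.add(state ^ (1 << i))
        return out

    def is_fixed_point(self, state: int) -> bool:
        return not self.successors(state)

    # -- construction helpers ----------------------------------------------
    @staticmethod
    def from_rules(rules: dict[str, str], order: list[str] | None = None) -> "BooleanSystem":
        names = list(order) if order is not None else list(rules)
        exprs = {t: parse_expression(e) for t, e in rules.items()}
        funcs = {t: BoolFunc.from_expr(node) for t, node in exprs.items()}
        return BooleanSystem(tuple(names), funcs, exprs)

    def restricted(self, assignment: dict[str, int]) -> "BooleanSystem | None":
        """Residual system with some variables pinned to constants.

        Returns None if every variable is pinned.
        """
        keep = tuple(v for v in self.variables if v not in assignment)
        if not keep:
            return None
        funcs = {v: self.functions[v].restrict(assignment) for v in keep}
        return BooleanSystem(keep, funcs)


def asynchronous_successors(sys: BooleanSystem, state: int) -> set[int]:
    """Module-level alias for :meth:`BooleanSystem.successors`."""
    return sys.successors(state)


# ---------------------------------------------------------------------------
# BoolNet-style rule files: one "target, expression" line per variable,
# '#' comments, optional "targets, factors" header.  Also accepts '=' or '*='
# as the separator for interoperability.
# ---------------------------------------------------------------------------

def parse_bnet(text: str) -> BooleanSystem:
    if not text.strip():
        raise BnetError("empty rule file")
    order: list[str] = []
    rules: dict[str, tuple] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," in line:
            target, expr_text = line.split(",", 1)
        elif "*=" in line:
            target, expr_text = line.split("*=", 1)
        elif "=" in line:
            target, expr_text = line.split("=", 1)
        else:
            raise BnetError("expected 'target, expression'", lineno)
        target = target.strip().rstrip("*").strip()
        if lineno == 1 and target.lower() == "targets" and expr_text.strip().lower() == "factors":
            continue
        if not target or not all(c.isalnum() or c in "._" for c in target):
            raise BnetError(f"bad target name {target!r}", lineno)
        if target in rules:
            raise BnetError(f"duplicate target {target!r}", lineno)
        try:
            node = parse_expression(expr_text)
        except ExpressionSyntaxError as exc:
            raise BnetError(f"syntax error in rule for {target!r}: {exc}", lineno) from exc
        order.append(target)
        rules[target] = node
    if not order:
        raise BnetError("no rules found")
    declared = set(order)
    for lineno_guess, (target, node) in enumerate(rules.items(), start=1):
        missing = expr_variables(node) - declared
        if missing:
            raise BnetError(
                f"rule for {target!r} references unknown variable(s) {sorted(missing)}"
            )
    funcs = {t: BoolFunc.from_expr(node) for t, node in rules.items()}
    return BooleanSystem(tuple(order), funcs, rules)


def write_bnet(sys: BooleanSystem, canonical: bool = False) -> str:
    """Serialize back to the rule-file dialect.

    With ``canonical=True`` every function is printed in Blake canonical DNF;
    otherwise the parsed syntax tree is reused when available.
    """
    lines = []
    for v in sys.variables:
        if not canonical and sys.source_exprs and v in sys.source_exprs:
            rhs = expr_to_str(sys.source_exprs[v])
        else:
            rhs = sys.functions[v].to_dnf_str()
        lines.append(f"{v}, {rhs}")
    return "\n".join(lines) + "\n"
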