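"""Parity and time-reversal transformations of Boolean systems.

Parity is the global change of variables X_i -> !X_i, sending update
functions f_i to the functions f'_i(X) = !f_i(!X); the STG of the image is
the original STG with every state bit-flipped.  Parity is an involution.

Time reversal sends f_i to f_i^-(X) = !f_i(X with X_i := !X_i); the STG of
the time-reversed system is the original STG with all change-edges reversed.
Time reversal is also an involution, fixed points of the time reversal are
exactly the Garden-of-Eden (in-degree-zero) states of the forward system,
and self-regulation does not change sign while every other interaction does.
"""

from __future__ import annotations

from .expressions import BoolFunc
from .system import BooleanSystem

__all__ = ["parity_transform", "time_reverse", "parity_func", "time_reverse_func"]


def parity_func(f: BoolFunc) -> BoolFunc:
    """f'(X) = !f(!X) on the truth table."""
    k = f.arity
    size = 1 << k
    full = size - 1
    table = 0
    for idx in range(size):
        if not (f.table >> (idx ^ full)) & 1:
            table |= 1 << idx
    return BoolFunc(f.inputs, table)


def time_reverse_func(f: BoolFunc, own_name: str) -> BoolFunc:
    """f^-(X) = !f(X with own variable negated)."""
    if own_name in f.inputs:
        j = f.inputs.index(own_name)
        size = 1 << f.arity
        table = 0
        for idx in range(size):
            if (f.table >> (idx ^ (1 << j))) & 1:
                table |= 1 << idx
        f = BoolFunc(f.inputs, table)
    return f.negate()._canonicalize()


def parity_transform(sys: BooleanSystem) -> BooleanSystem:
    """The parity image of a system (an involution)."""
    funcs = {v: parity_func(sys.functions[v]) for v in sys.variables}
    return BooleanSystem(sys.variables, funcs)


def time_reverse(sys: BooleanSystem) -> BooleanSystem:
    """The time-reversed system (an involution up to truth-table equality)."""
    funcs = {v: time_reverse_func(sys.functions[v], v) for v in sys.variables}
    return BooleanSystem(sys.variables, funcs)
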