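"""Boolean expressions and truth-table-backed functions.

Update functions are held in a dual representation: a syntax tree (as parsed,
used for display and round-tripping) and a canonical truth table over the
function's referenced inputs only.  The truth table is the computational
workhorse: restriction, composition, negation, and equality all operate on
it.  Tables are stored as Python integers interpreted as bit vectors; entry
``idx`` holds the function value for the input assignment whose j-th input
(in ``inputs`` order) equals bit j of ``idx``.

Functions with more than :data:`MAX_INPUTS` referenced inputs are refused:
materializing their tables is the wrong tool, and callers are expected to
fall back to bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

MAX_INPUTS = 20

__all__ = [
    "MAX_INPUTS",
    "ArityError",
    "ExpressionSyntaxError",
    "BoolFunc",
    "parse_expression",
    "expr_variables",
    "expr_to_str",
]


class ArityError(ValueError):
    """A truth table over more than MAX_INPUTS inputs was requested."""


class ExpressionSyntaxError(ValueError):
    """Malformed Boolean expression text."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


# ---------------------------------------------------------------------------
# Expression AST: nested tuples.
#   ("const", 0|1) | ("var", name) | ("not", x) | ("and", a, b) | ("or", a, b)
# ---------------------------------------------------------------------------

_OP_WORDS = {"not": "!", "and": "&", "or": "|", "true": "1", "false": "0"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "!~":
            tokens.append(("NOT", c, i))
            i += 1
        elif c == "&":
            i += 2 if text[i : i + 2] == "&&" else 1
            tokens.append(("AND", "&", i))
        elif c == "|":
            i += 2 if text[i : i + 2] == "||" else 1
            tokens.append(("OR", "|", i))
        elif c == "*":  # product/sum spellings used by some BoolNet exports
            tokens.append(("AND", "&", i))
            i += 1
        elif c == "+":
            tokens.append(("OR", "|", i))
            i += 1
        elif c == "(":
            tokens.append(("LP", c, i))
            i += 1
        elif c == ")":
            tokens.append(("RP", c, i))
            i += 1
        elif c in "01" and (i + 1 >= n or not (text[i + 1].isalnum() or text[i + 1] == "_")):
            tokens.append(("CONST", c, i))
            i += 1
        elif c.isalpha() or c == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] in "._"):
                j += 1
            word = text[i:j]
            low = word.lower()
            if low in _OP_WORDS:
                sym = _OP_WORDS[low]
                kind = {"!": "NOT", "&": "AND", "|": "OR", "0": "CONST", "1": "CONST"}[sym]
                tokens.append((kind, sym, i))
            else:
                tokens.append(("NAME", word, i))
            i = j
        else:
            raise ExpressionSyntaxError(f"unexpected character {c!r}", i)
    return tokens


def parse_expression(text: str) -> tuple:
    """Parse expression text into an AST.

    Grammar (standard precedence, NOT > AND > OR)::

        expr   := term ( OR term )*
        term   := factor ( AND factor )*
        factor := NOT factor | '(' expr ')' | NAME | CONST
    """
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else ("EOF", "", len(text))

    def take(kind):
        nonlocal pos
        tok = peek()
        if tok[0] != kind:
            raise ExpressionSyntaxError(f"expected {kind}, found {tok[1]!r}", tok[2])
        pos += 1
        return tok

    def factor():
        tok = peek()
        if tok[0] == "NOT":
            take("NOT")
            return ("not", factor())
        if tok[0] == "LP":
            take("LP")
            node = expr()
            take("RP")
            return node
        if tok[0] == "NAME":
            take("NAME")
            return ("var", tok[1])
        if tok[0] == "CONST":
            take("CONST")
            return ("const", int(tok[1]))
        raise ExpressionSyntaxError(f"unexpected token {tok[1]!r}", tok[2])

    def term():
        node = factor()
        while peek()[0] == "AND":
            take("AND")
            node = ("and", node, factor())
        return node

    def expr():
        node = term()
        while peek()[0] == "OR":
            take("OR")
            node = ("or", node, term())
        return node

    node = expr()
    tok = peek()
    if tok[0] != "EOF":
        raise ExpressionSyntaxError(f"trailing input at {tok[1]!r}", tok[2])
    return node


def expr_variables(node: tuple) -> set[str]:
    kind = node[0]
    if kind == "var":
        return {node[1]}
    if kind == "const":
        return set()
    out: set[str] = set()
    for child in node[1:]:
        out |= expr_variables(child)
    return out


def expr_to_str(node: tuple) -> str:
    kind = node[0]
    if kind == "const":
        return str(node[1])
    if kind == "var":
        return node[1]
    if kind == "not":
        inner = expr_to_str(node[1])
        if node[1][0] in ("and", "or"):
            inner = f"({inner})"
        return f"!{inner}"
    sep = " & " if kind == "and" else " | "
    parts = []
    for child in node[1:]:
        s = expr_to_str(child)
        if kind == "and" and child[0] == "or":
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)


def _eval_ast(node: tuple, env: Mapping[str, int]) -> int:
    kind = node[0]
    if kind == "const":
        return node[1]
    if kind == "var":
        return env[node[1]]
    if kind == "not":
        return 1 - _eval_ast(node[1], env)
    if kind == "and":
        return _eval_ast(node[1], env) & _eval_ast(node[2], env)
    return _eval_ast(node[1], env) | _eval_ast(node[2], env)


def _to_bits(table: int, k: int) -> np.ndarray:
    size = 1 << k
    nbytes = (size + 7) // 8
    raw = np.frombuffer(table.to_bytes(nbytes, "little"), dtype=np.uint8)
    return np.unpackbits(raw, bitorder="little")[:size]


def _from_bits(bits: np.ndarray) -> int:
    return int.from_bytes(np.packbits(bits, bitorder="little").tobytes(), "little")


@dataclass(frozen=True)
class BoolFunc:
    """A Boolean function over a fixed, sorted tuple of named inputs.

    ``table`` is an integer bit vector of length ``2**len(inputs)``; fictitious
    inputs are always dropped, so two equal functions compare equal regardless
    of how they were built.
    """

    inputs: tuple[str, ...]
    table: int

    # -- constructors -----------------------------------------------------
    @staticmethod
    def constant(value: int) -> "BoolFunc":
        return BoolFunc((), 1 if value else 0)

    @staticmethod
    def variable(name: str) -> "BoolFunc":
        return BoolFunc((name,), 0b10)

    @staticmethod
    def from_table(inputs: Iterable[str], table: int) -> "BoolFunc":
        inputs = tuple(inputs)
        if len(inputs) > MAX_INPUTS:
            raise ArityError(f"{len(inputs)} inputs exceeds the {MAX_INPUTS}-input budget")
        f = BoolFunc(inputs, table)
        return f._canonicalize()

    @staticmethod
    def from_expr(node: tuple) -> "BoolFunc":
        names = sorted(expr_variables(node))
        if len(names) > MAX_INPUTS:
            raise ArityError(f"{len(names)} inputs exceeds the {MAX_INPUTS}-input budget")
        k = len(names)
        table = 0
        for idx in range(1 << k):
            env = {name: (idx >> j) & 1 for j, name in enumerate(names)}
            if _eval_ast(node, env):
                table |= 1 << idx
        return BoolFunc(tuple(names), table)._canonicalize()

    @staticmethod
    def parse(text: str) -> "BoolFunc":
        return BoolFunc.from_expr(parse_expression(text))

    # -- canonical form ---------------------------------------------------
    def _canonicalize(self) -> "BoolFunc":
        """Sort inputs and drop fictitious ones."""
        k = len(self.inputs)
        inputs, table = self.inputs, self.table
        order = sorted(range(k), key=lambda j: inputs[j])
        if [inputs[j] for j in order] != list(inputs):
            table = self._permute(table, k, order)
            inputs = tuple(inputs[j] for j in order)
        # drop inputs the table does not actually depend on
        j = 0
        while j < len(inputs):
            k = len(inputs)
            lo_as = self._extract(table, j, k, 0)
            hi_as = self._extract(table, j, k, 1)
            if lo_as == hi_as:
                inputs = inputs[:j] + inputs[j + 1 :]
                table = lo_as
            else:
                j += 1
        if inputs == self.inputs and table == self.table:
            return self
        return BoolFunc(inputs, table)

    @staticmethod
    def _permute(table: int, k: int, order: list[int]) -> int:
        """Reindex the table so new input j is old input order[j]."""
        if k >= 8:
            idx = np.arange(1 << k, dtype=np.int64)
            new_idx = np.zeros(1 << k, dtype=np.int64)
            for new_j, old_j in enumerate(order):
                new_idx |= ((idx >> old_j) & 1) << new_j
            out = np.zeros(1 << k, dtype=np.uint8)
            out[new_idx] = _to_bits(table, k)
            return _from_bits(out)
        new_table = 0
        for idx in range(1 << k):
            new_idx = 0
            for new_j, old_j in enumerate(order):
                if (idx >> old_j) & 1:
                    new_idx |= 1 << new_j
            if (table >> idx) & 1:
                new_table |= 1 << new_idx
        return new_table

    @staticmethod
    def _extract(table: int, j: int, k: int, val: int) -> int:
        """Cofactor table with input j fixed to val (inputs renumbered)."""
        if k >= 8:
            arr = _to_bits(table, k).reshape([2] * k)  # axis k-1-j is input j
            return _from_bits(np.take(arr, val, axis=k - 1 - j).ravel())
        out = 0
        pos = 0
        for idx in range(1 << k):
            if (idx >> j) & 1 == val:
                if (table >> idx) & 1:
                    out |= 1 << pos
                pos += 1
        return out

    # -- queries ----------------------------------------------------------
    @property
    def arity(self) -> int:
        return len(self.inputs)

    def is_constant(self) -> bool:
        return not self.inputs

    def as_constant(self) -> int | None:
        if self.inputs:
            return None
        return self.table & 1

    def __call__(self, env: Mapping[str, int]) -> int:
        idx = 0
        for j, name in enumerate(self.inputs):
            if env[name]:
                idx |= 1 << j
        return (self.table >> idx) & 1

    def table_array(self) -> np.ndarray:
        """Truth table as a uint8 numpy array of length 2**arity."""
        return _to_bits(self.table, self.arity)

    # -- algebra ----------------------------------------------------------
    def negate(self) -> "BoolFunc":
        mask = (1 << (1 << self.arity)) - 1
        return BoolFunc(self.inputs, self.table ^ mask)

    def restrict(self, assignment: Mapping[str, int]) -> "BoolFunc":
        """Partially evaluate, fixing some inputs to constants."""
        return self.restrict_fast(assignment)._canonicalize()

    def restrict_fast(self, assignment: Mapping[str, int]) -> "BoolFunc":
        """Restriction without dropping fictitious inputs (hot path)."""
        inputs, table = self.inputs, self.table
        for name, val in sorted(assignment.items(), reverse=True):
            if name not in inputs:
                continue
            j = inputs.index(name)
            table = self._extract(table, j, len(inputs), 1 if val else 0)
            inputs = inputs[:j] + inputs[j + 1 :]
        return BoolFunc(inputs, table)

    def constant_value(self) -> int | None:
        """0/1 when the table is constant-valued (fictitious inputs allowed)."""
        if self.table == 0:
            return 0
        if self.table == (1 << (1 << self.arity)) - 1:
            return 1
        return None

    def compose(self, name: str, other: "BoolFunc") -> "BoolFunc":
        """Substitute ``other`` for input ``name`` (Shannon expansion)."""
        if name not in self.inputs:
            return self
        j = self.inputs.index(name)
        k = len(self.inputs)
        rest = self.inputs[:j] + self.inputs[j + 1 :]
        lo = BoolFunc(rest, self._extract(self.table, j, k, 0))
        hi = BoolFunc(rest, self._extract(self.table, j, k, 1))
        # f = (!g & f0) | (g & f1)
        return other.negate().and_(lo).or_(other.and_(hi))

    def _align(self, other: "BoolFunc") -> tuple[tuple[str, ...], int, int]:
        names = tuple(sorted(set(self.inputs) | set(other.inputs)))
        if len(names) > MAX_INPUTS:
            raise ArityError(f"{len(names)} inputs exceeds the {MAX_INPUTS}-input budget")

        def lift(f: BoolFunc) -> int:
            posmap = [names.index(v) for v in f.inputs]
            k = len(names)
            if k >= 8:
                idx = np.arange(1 << k, dtype=np.int64)
                sub = np.zeros(1 << k, dtype=np.int64)
                for j, p in enumerate(posmap):
                    sub |= ((idx >> p) & 1) << j
                return _from_bits(_to_bits(f.table, f.arity)[sub])
            out = 0
            for idx in range(1 << k):
                sub = 0
                for j, p in enumerate(posmap):
                    if (idx >> p) & 1:
                        sub |= 1 << j
                if (f.table >> sub) & 1:
                    out |= 1 << idx
            return out

        return names, lift(self), lift(other)

    def and_(self, other: "BoolFunc") -> "BoolFunc":
        names, a, b = self._align(other)
        return BoolFunc(names, a & b)._canonicalize()

    def or_(self, other: "BoolFunc") -> "BoolFunc":
        names, a, b = self._align(other)
        return BoolFunc(names, a | b)._canonicalize()

    # -- display ----------------------------------------------------------
    def to_dnf_str(self) -> str:
        """Blake-canonical disjunctive normal form (all prime implicants)."""
        from .primes import prime_implicants_of_func

        const = self.constant_value()
        if const is not None:
            return str(const)
        clauses = []
        for pi in prime_implicants_of_func(self):
            lits = [name if val else f"!{name}" for name, val in sorted(pi)]
            clauses.append(" & ".join(lits))
        return " | ".join(clauses)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BoolFunc({self.to_dnf_str()!r})"
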