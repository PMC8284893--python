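"""Prime implicant computation (Quine-McCluskey, full Blake canonical form).

A prime implicant of f is an irreducible conjunction of literals that forces
f to 1.  We return *all* prime implicants, not a minimal cover: the
parity-expanded network needs the complete set, since each prime implicant of
f_i (resp. of its negation) becomes one hyperedge into the virtual node
(i, 1) (resp. (i, 0)).

Conventions for degenerate functions: the constant-1 function has the single
empty implicant (a tautology hyperedge with no parents); the constant-0
function has none.
"""

from __future__ import annotations

from .expressions import BoolFunc

Literal = tuple[str, int]  # (variable name, value)
Implicant = frozenset[Literal]

__all__ = ["prime_implicants_of_func", "prime_implicants"]


def _qm_all_primes(minterms: list[int], k: int) -> list[tuple[int, int]]:
    """All prime cubes as (values, dontcare_mask) pairs over k bits."""
    primes: set[tuple[int, int]] = set()
    current: set[tuple[int, int]] = {(m, 0) for m in minterms}
    while current:
        merged: set[tuple[int, int]] = set()
        used: set[tuple[int, int]] = set()
        # group by (dontcare mask, popcount of values) to limit pairing
        groups: dict[tuple[int, int], list[int]] = {}
        for values, dc in current:
            groups.setdefault((dc, bin(values).count("1")), []).append(values)
        for (dc, ones), vals in groups.items():
            partner = groups.get((dc, ones + 1), [])
            for v in vals:
                for w in partner:
                    diff = v ^ w
                    if diff and (diff & (diff - 1)) == 0 and not (diff & dc):
                        merged.add((v & ~diff, dc | diff))
                        used.add((v, dc))
                        used.add((w, dc))
        primes |= current - used
        current = merged
    return sorted(primes)


def prime_implicants_of_func(f: BoolFunc) -> list[Implicant]:
    """Complete prime implicant set of a truth-table function.

    Deterministically ordered (by size, then by sorted literals).
    """
    const = f.constant_value()
    if const == 0:
        return []
    if const == 1:
        return [frozenset()]
    k = f.arity
    minterms = [idx for idx in range(1 << k) if (f.table >> idx) & 1]
    cubes = _qm_all_primes(minterms, k)
    out = []
    for values, dc in cubes:
        lits = frozenset(
            (f.inputs[j], (values >> j) & 1) for j in range(k) if not (dc >> j) & 1
        )
        out.append(lits)
    out.sort(key=lambda s: (len(s), sorted(s)))
    return out


def prime_implicants(expr: "str | tuple | BoolFunc") -> list[Implicant]:
    """Prime implicants of an expression, expression text, or function."""
    if isinstance(expr, BoolFunc):
        f = expr
    elif isinstance(expr, str):
        f = BoolFunc.parse(expr)
    else:
        f = BoolFunc.from_expr(expr)
    return prime_implicants_of_func(f)
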