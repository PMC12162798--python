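"""Truth-table level utilities for Boolean functions.

A Boolean function of ``k`` ordered inputs is stored as a flat numpy array of
``2**k`` values in {0, 1}.  The *first* input is the least significant bit of
the table index, i.e. the output for the input vector ``(x_0, ..., x_{k-1})``
is ``table[sum(x_j << j)]``.

This module provides expression parsing and evaluation (the ``!``, ``&``,
``|`` algebra used in .bnet files), essential-input pruning, edge-sign
analysis, prime implicants (Quine-McCluskey), and DNF emission.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExpressionError",
    "parse_expression",
    "expression_names",
    "table_from_expression",
    "normalize_table",
    "input_signs",
    "prime_implicants",
    "covering_implicants",
    "dnf_from_table",
]

NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<op>[01()!&|]))")


class ExpressionError(ValueError):
    """Raised for malformed Boolean expressions."""


def _tokenize(expr: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip():
                raise ExpressionError(
                    f"unexpected character {expr[pos:].strip()[0]!r} in {expr!r}"
                )
            break
        tokens.append(m.group(m.lastgroup))
        pos = m.end()
    return tokens


def parse_expression(expr: str):
    """Parse an expression into an AST of nested tuples.

    Grammar (lowest to highest precedence): ``or := and ('|' and)*``,
    ``and := unary ('&' unary)*``, ``unary := '!' unary | atom``,
    ``atom := name | '0' | '1' | '(' or ')'``.
    """
    tokens = _tokenize(expr)
    if not tokens:
        raise ExpressionError(f"empty expression {expr!r}")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def parse_or():
        node = parse_and()
        while peek() == "|":
            take()
            node = ("or", node, parse_and())
        return node

    def parse_and():
        node = parse_unary()
        while peek() == "&":
            take()
            node = ("and", node, parse_unary())
        return node

    def parse_unary():
        tok = peek()
        if tok == "!":
            take()
            return ("not", parse_unary())
        return parse_atom()

    def parse_atom():
        tok = take()
        if tok == "(":
            node = parse_or()
            if take() != ")":
                raise ExpressionError(f"unbalanced parentheses in {expr!r}")
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok is not None and NAME_RE.fullmatch(tok):
            return ("var", tok)
        raise ExpressionError(f"unexpected token {tok!r} in {expr!r}")

    ast = parse_or()
    if pos != len(tokens):
        raise ExpressionError(f"trailing tokens {tokens[pos:]} in {expr!r}")
    return ast


def expression_names(expr: str) -> list[str]:
    """Variable names referenced by an expression, in order of appearance."""
    names: list[str] = []

    def walk(node):
        if node[0] == "var":
            if node[1] not in names:
                names.append(node[1])
        elif node[0] == "not":
            walk(node[1])
        elif node[0] in ("and", "or"):
            walk(node[1])
            walk(node[2])

    walk(parse_expression(expr))
    return names


def table_from_expression(expr: str, inputs: Sequence[str] | None = None,
                          max_inputs: int = 20):
    """Evaluate an expression over the full cube of its inputs.

    Returns ``(inputs, table)``.  If ``inputs`` is not given, the variables
    appearing in the expression are used in order of appearance.  The table is
    *not* pruned of non-essential inputs here.
    """
    ast = parse_expression(expr)
    if inputs is None:
        inputs = expression_names(expr)
    inputs = list(inputs)
    if len(inputs) > max_inputs:
        raise ExpressionError(
            f"expression has {len(inputs)} inputs; the supported maximum is {max_inputs}"
        )
    k = len(inputs)
    states = np.arange(2 ** k, dtype=np.int64)
    columns = {name: ((states >> j) & 1).astype(np.uint8)
               for j, name in enumerate(inputs)}

    def ev(node):
        tag = node[0]
        if tag == "var":
            if node[1] not in columns:
                raise ExpressionError(f"variable {node[1]!r} not among inputs")
            return columns[node[1]]
        if tag == "const":
            return np.full(2 ** k, node[1], dtype=np.uint8)
        if tag == "not":
            return (1 - ev(node[1])).astype(np.uint8)
        if tag == "and":
            return ev(node[1]) & ev(node[2])
        if tag == "or":
            return ev(node[1]) | ev(node[2])
        raise AssertionError(tag)

    return tuple(inputs), ev(ast)


def _as_cube(table: np.ndarray, k: int) -> np.ndarray:
    # C-order reshape puts input 0 (LSB of the index) on the *last* axis,
    # so input j lives on axis k - 1 - j.
    return table.reshape((2,) * k) if k else table.reshape(())


def essential_inputs(table: np.ndarray) -> list[int]:
    """Indices of inputs whose flip changes the output for some input state."""
    k = int(np.log2(len(table))) if len(table) > 1 else 0
    cube = _as_cube(np.asarray(table), k)
    ess = []
    for j in range(k):
        axis = k - 1 - j
        lo = np.take(cube, 0, axis=axis)
        hi = np.take(cube, 1, axis=axis)
        if np.any(lo != hi):
            ess.append(j)
    return ess


def normalize_table(inputs: Sequence[str], table) -> tuple[tuple[str, ...], np.ndarray]:
    """Prune non-essential inputs from a truth table.

    The relative order of the remaining inputs is preserved.
    """
    table = np.asarray(table, dtype=np.uint8).ravel()
    k = len(inputs)
    if len(table) != 2 ** k:
        raise ValueError(
            f"table length {len(table)} does not match {k} inputs (expected {2 ** k})"
        )
    ess = essential_inputs(table)
    if len(ess) == k:
        return tuple(inputs), table
    cube = _as_cube(table, k)
    # drop higher axes first so remaining axis indices stay valid
    for j in range(k):
        if j not in ess:
            cube = np.take(cube, 0, axis=k - 1 - j)
    new_inputs = tuple(inputs[j] for j in ess)
    return new_inputs, np.ascontiguousarray(cube).ravel().astype(np.uint8)


def input_signs(inputs: Sequence[str], table: np.ndarray) -> dict[str, int]:
    """Sign of each (essential) input: +1 activating, -1 inhibiting, 0 dual.

    The sign is determined by exhaustive flip analysis over the input cube:
    +1 if every 0->1 flip of the input weakly increases the output (and some
    flip strictly increases it), -1 symmetrically, 0 if flips both increase
    and decrease the output depending on context.
    """
    k = len(inputs)
    cube = _as_cube(np.asarray(table, dtype=np.int8), k)
    signs: dict[str, int] = {}
    for j, name in enumerate(inputs):
        axis = k - 1 - j
        diff = np.take(cube, 1, axis=axis).astype(np.int8) - np.take(cube, 0, axis=axis)
        inc = bool(np.any(diff > 0))
        dec = bool(np.any(diff < 0))
        if inc and dec:
            signs[name] = 0
        elif inc:
            signs[name] = 1
        elif dec:
            signs[name] = -1
        # non-essential inputs are simply omitted
    return signs


def prime_implicants(table, value: int = 1) -> list[tuple[int, int]]:
    """Prime implicants of the ``value``-set of a truth table.

    Each implicant is a pair ``(care_mask, bits)``: input ``j`` is fixed to
    ``(bits >> j) & 1`` when bit ``j`` of ``care_mask`` is set, and is a
    wildcard otherwise.  Quine-McCluskey expansion: terms differing in one
    cared bit are merged until no merge applies; unmerged terms are prime.
    """
    table = np.asarray(table).ravel()
    k = int(np.log2(len(table))) if len(table) > 1 else 0
    full = (1 << k) - 1
    terms = {(full, int(m)) for m in np.nonzero(table == value)[0]}
    if len(table) == 1:
        return [(0, 0)] if table[0] == value else []
    primes: set[tuple[int, int]] = set()
    while terms:
        merged_from: set[tuple[int, int]] = set()
        next_terms: set[tuple[int, int]] = set()
        for mask, bits in terms:
            for j in range(k):
                b = 1 << j
                if mask & b and (mask, bits ^ b) in terms:
                    merged_from.add((mask, bits))
                    next_terms.add((mask & ~b, bits & ~b))
        primes |= terms - merged_from
        terms = next_terms
    return sorted(primes)


def covering_implicants(primes: Iterable[tuple[int, int]], state: int) -> list[tuple[int, int]]:
    """The implicants among ``primes`` that cover input ``state``."""
    return [(mask, bits) for mask, bits in primes if (state & mask) == bits]


def dnf_from_table(inputs: Sequence[str], table: np.ndarray) -> str:
    """A disjunctive normal form built from a greedy prime-implicant cover."""
    table = np.asarray(table).ravel()
    if len(table) == 1 or not len(inputs):
        return str(int(table.ravel()[0]))
    if np.all(table == 0):
        return "0"
    if np.all(table == 1):
        return "1"
    primes = prime_implicants(table, value=1)
    minterms = [int(m) for m in np.nonzero(table == 1)[0]]
    uncovered = set(minterms)
    chosen: list[tuple[int, int]] = []
    while uncovered:
        best = max(primes, key=lambda p: (len([m for m in uncovered if (m & p[0]) == p[1]]),
                                          -p[0]))
        cover = [m for m in uncovered if (m & best[0]) == best[1]]
        if not cover:  # pragma: no cover - cannot happen for a correct prime set
            raise AssertionError("prime implicant cover failed")
        chosen.append(best)
        uncovered -= set(cover)

    def term(mask: int, bits: int) -> str:
        lits = []
        for j, name in enumerate(inputs):
            if mask & (1 << j):
                lits.append(name if bits & (1 << j) else f"!{name}")
        return " & ".join(lits)

    return " | ".join(term(m, b) for m, b in sorted(chosen))
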