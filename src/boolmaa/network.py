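"""Boolean network representation, .bnet parsing/serialization, and signed
interaction-graph inference.

A :class:`BooleanNetwork` holds an ordered tuple of variable names and one
update function per variable.  Functions are stored canonically: the input
list is sorted by declaration order of the variables, every listed input is
essential (flipping it changes the output somewhere), and the truth table is
a flat array indexed with the first input as the least significant bit.

States of the network are encoded as integers in which bit ``i`` carries the
value of variable ``i``; the printed form (``state_to_str``) lists variable 0
first, matching the usual ``0*1*`` subspace convention.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from . import logic

__all__ = [
    "BooleanNetwork",
    "BnetParseError",
    "parse_bnet",
    "write_bnet",
    "interaction_graph",
    "state_to_str",
    "str_to_state",
]

#: Hard cap on the in-degree of a single update function.  Truth tables are
#: explicit, so parsing and substitution fail loudly beyond this.
MAX_INPUTS = 20


class BnetParseError(ValueError):
    """Raised when a .bnet document cannot be parsed."""


def state_to_str(state: int, n: int) -> str:
    """Binary string of a state, variable 0 first."""
    return "".join("1" if (state >> i) & 1 else "0" for i in range(n))


def str_to_state(s: str) -> int:
    """Inverse of :func:`state_to_str`."""
    return sum(1 << i for i, c in enumerate(s) if c == "1")


class BooleanNetwork:
    """An ordered collection of Boolean variables with update functions.

    Parameters
    ----------
    functions:
        Mapping from variable name to ``(inputs, table)``; the table gives the
        function's output over the full cube of the listed inputs (first input
        = least significant index bit).  Non-essential inputs are pruned and
        inputs are re-sorted into declaration order on construction.
    variables:
        Declaration order.  Defaults to the mapping's insertion order.
    """

    def __init__(self,
                 functions: Mapping[str, tuple[Sequence[str], Sequence[int]]],
                 variables: Sequence[str] | None = None):
        if variables is None:
            variables = list(functions)
        if set(variables) != set(functions):
            raise ValueError("variables and functions must cover the same names")
        if len(set(variables)) != len(variables):
            raise ValueError("duplicate variable name")
        self.variables: tuple[str, ...] = tuple(variables)
        self._index = {v: i for i, v in enumerate(self.variables)}
        funcs: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
        for v in self.variables:
            inputs, table = functions[v]
            inputs = tuple(inputs)
            for u in inputs:
                if u not in self._index:
                    raise ValueError(f"function of {v!r} uses undeclared variable {u!r}")
            if len(set(inputs)) != len(inputs):
                raise ValueError(f"function of {v!r} lists a repeated input")
            if len(inputs) > MAX_INPUTS:
                raise ValueError(
                    f"function of {v!r} has {len(inputs)} inputs; maximum is {MAX_INPUTS}")
            inputs, table = self._canonicalize(inputs, table)
            funcs[v] = (inputs, table)
        self.functions = funcs
        self._values_cache: np.ndarray | None = None

    # -- construction helpers -------------------------------------------------

    def _canonicalize(self, inputs, table):
        table = np.asarray(table, dtype=np.uint8).ravel()
        if len(table) != 2 ** len(inputs):
            raise ValueError("truth-table length must be 2**len(inputs)")
        order = sorted(range(len(inputs)), key=lambda j: self._index[inputs[j]])
        if order != list(range(len(inputs))):
            k = len(inputs)
            cube = table.reshape((2,) * k) if k else table
            # axis of input j is k-1-j; permute inputs into declaration order
            axes = [k - 1 - order[k - 1 - a] for a in range(k)]
            cube = np.transpose(cube, axes=axes)
            inputs = tuple(inputs[j] for j in order)
            table = np.ascontiguousarray(cube).ravel()
        return logic.normalize_table(inputs, table)

    @classmethod
    def from_expressions(cls, rules: Mapping[str, str] | Iterable[tuple[str, str]]
                         ) -> "BooleanNetwork":
        """Build a network from ``{name: expression}`` rules."""
        pairs = list(rules.items()) if isinstance(rules, Mapping) else list(rules)
        declared = [name for name, _ in pairs]
        functions = {}
        for name, expr in pairs:
            inputs, table = logic.table_from_expression(expr, max_inputs=MAX_INPUTS)
            functions[name] = (inputs, table)
        return cls(functions, variables=declared)

    # -- basic queries --------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.variables)

    def index(self, name: str) -> int:
        return self._index[name]

    def function(self, name: str) -> tuple[tuple[str, ...], np.ndarray]:
        return self.functions[name]

    def inputs(self, name: str) -> tuple[str, ...]:
        return self.functions[name][0]

    def has_self_input(self, name: str) -> bool:
        return name in self.functions[name][0]

    def n_edges(self) -> int:
        return sum(len(f[0]) for f in self.functions.values())

    # -- evaluation -----------------------------------------------------------

    def values_on_all_states(self) -> np.ndarray:
        """``(2**n, n)`` array: column ``i`` is f_i evaluated on every state."""
        if self._values_cache is None:
            n = self.n
            states = np.arange(1 << n, dtype=np.int64)
            vals = np.empty((1 << n, n), dtype=np.uint8)
            for i, v in enumerate(self.variables):
                inputs, table = self.functions[v]
                idx = np.zeros(1 << n, dtype=np.int64)
                for j, u in enumerate(inputs):
                    idx |= ((states >> self._index[u]) & 1) << j
                vals[:, i] = table[idx]
            self._values_cache = vals
        return self._values_cache

    def evaluate(self, name: str, state: int) -> int:
        """Evaluate one update function on one (global) state."""
        inputs, table = self.functions[name]
        idx = 0
        for j, u in enumerate(inputs):
            idx |= ((state >> self._index[u]) & 1) << j
        return int(table[idx])

    # -- dunder ---------------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanNetwork):
            return NotImplemented
        if self.variables != other.variables:
            return False
        for v in self.variables:
            si, st = self.functions[v]
            oi, ot = other.functions[v]
            if si != oi or not np.array_equal(st, ot):
                return False
        return True

    def __repr__(self) -> str:
        return f"BooleanNetwork({', '.join(self.variables)})"


# -- .bnet I/O ----------------------------------------------------------------

def parse_bnet(text: str) -> BooleanNetwork:
    """Parse a .bnet document ("target, expression" lines).

    Lines starting with ``#`` are comments; an optional ``targets, factors``
    header is ignored.  Undefined variables, duplicate targets and malformed
    expressions raise :class:`BnetParseError` naming the offending line.
    """
    pairs: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "," not in line:
            raise BnetParseError(f"line {lineno}: expected 'target, expression'")
        name, expr = line.split(",", 1)
        name, expr = name.strip(), expr.strip()
        if name.lower() == "targets" and expr.lower() == "factors":
            continue
        if not logic.NAME_RE.fullmatch(name):
            raise BnetParseError(f"line {lineno}: invalid variable name {name!r}")
        if name in seen:
            raise BnetParseError(f"line {lineno}: duplicate target {name!r}")
        if not expr:
            raise BnetParseError(f"line {lineno}: empty expression for {name!r}")
        seen.add(name)
        pairs.append((name, expr, lineno))

    functions = {}
    for name, expr, lineno in pairs:
        try:
            refs = logic.expression_names(expr)
        except logic.ExpressionError as exc:
            raise BnetParseError(f"line {lineno}: {exc}") from exc
        for ref in refs:
            if ref not in seen:
                raise BnetParseError(
                    f"line {lineno}: undefined variable {ref!r} in rule for {name!r}")
        if len(refs) > MAX_INPUTS:
            raise BnetParseError(
                f"line {lineno}: rule for {name!r} has {len(refs)} inputs; "
                f"maximum is {MAX_INPUTS}")
        try:
            inputs, table = logic.table_from_expression(expr, max_inputs=MAX_INPUTS)
        except logic.ExpressionError as exc:
            raise BnetParseError(f"line {lineno}: {exc}") from exc
        functions[name] = (inputs, table)
    return BooleanNetwork(functions, variables=[name for name, _, _ in pairs])


def write_bnet(net: BooleanNetwork, header: bool = True) -> str:
    """Serialize a network; expressions are prime-implicant DNF covers."""
    lines = ["targets, factors"] if header else []
    for v in net.variables:
        inputs, table = net.functions[v]
        lines.append(f"{v}, {logic.dnf_from_table(inputs, table)}")
    return "\n".join(lines) + "\n"


# -- interaction graph --------------------------------------------------------

def interaction_graph(net: BooleanNetwork) -> nx.DiGraph:
    """Signed interaction graph inferred from the update functions.

    Edge ``u -> v`` exists iff ``u`` is an essential input of ``f_v``; the
    ``sign`` attribute is +1 (activating), -1 (inhibiting) or 0 (dual),
    decided by exhaustive flip analysis.
    """
    g = nx.DiGraph()
    g.add_nodes_from(net.variables)
    for v in net.variables:
        inputs, table = net.functions[v]
        for u, sign in logic.input_signs(inputs, table).items():
            g.add_edge(u, v, sign=sign)
    return g
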