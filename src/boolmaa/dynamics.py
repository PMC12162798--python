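"""State transition graphs, attractors, trap spaces and motif avoidance.

Attractors are the terminal strongly connected components of the state
transition graph (STG).  Under asynchronous update each state has up to N
outgoing transitions (one per variable whose update changes the state;
self-transitions are omitted, so fixed points are the zero-out-degree
states).  A *trap space* is a subspace that the dynamics cannot leave; it is
a property of the update functions alone and therefore independent of the
update scheme.  A complex attractor whose smallest enclosing trap space is
not inclusion-minimal is *motif-avoidant* (MAA): it avoids every stable
configuration that would otherwise lock the network into a minimal trap
space.

Two interchangeable engines compute minimal trap spaces: an exhaustive scan
over all 3**N subspaces (the oracle, N <= 12) and a depth-first branching
search over partial assignments with consistency pruning (the default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import total_ordering
from itertools import product

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .network import BooleanNetwork, state_to_str

__all__ = [
    "Subspace",
    "Attractor",
    "MAAReport",
    "SizeGuardError",
    "CapacityError",
    "build_stg",
    "attractors",
    "is_trap_space",
    "smallest_enclosing_trap_space",
    "minimal_trap_spaces",
    "is_minimal_trap_space",
    "find_maas",
    "has_maa",
    "maa_metrics",
]

#: Explicit-STG guard: networks beyond this size are not analysed explicitly.
STG_VARIABLE_LIMIT = 22
#: Branching trap-space engine capacity.
BRANCHING_VARIABLE_LIMIT = 28
#: Brute-force (3**N scan) trap-space engine capacity.
BRUTE_FORCE_LIMIT = 12


class SizeGuardError(RuntimeError):
    """The network exceeds an explicit-state-space size guard."""


class CapacityError(RuntimeError):
    """The branching trap-space engine capacity was exceeded."""


# ---------------------------------------------------------------------------
# Subspaces
# ---------------------------------------------------------------------------

@total_ordering
class Subspace:
    """A hypercube of states: each variable is fixed to 0/1 or free (``*``).

    ``values[i]`` is 0, 1 or ``None`` for variable ``i`` (declaration order).
    """

    __slots__ = ("values",)

    def __init__(self, values):
        self.values = tuple(values)

    @classmethod
    def from_str(cls, s: str) -> "Subspace":
        return cls(None if c == "*" else int(c) for c in s)

    @classmethod
    def full(cls, n: int) -> "Subspace":
        return cls((None,) * n)

    @classmethod
    def from_state(cls, state: int, n: int) -> "Subspace":
        return cls(((state >> i) & 1 for i in range(n)))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def free_count(self) -> int:
        return sum(1 for v in self.values if v is None)

    @property
    def fixed(self) -> dict[int, int]:
        return {i: v for i, v in enumerate(self.values) if v is not None}

    @property
    def size(self) -> int:
        return 1 << self.free_count

    def contains_state(self, state: int) -> bool:
        return all((state >> i) & 1 == v
                   for i, v in enumerate(self.values) if v is not None)

    def contains_subspace(self, other: "Subspace") -> bool:
        """True iff ``other`` is a (not necessarily proper) sub-cube of self."""
        return all(other.values[i] == v
                   for i, v in enumerate(self.values) if v is not None)

    def states(self):
        """Iterate over all member states (exponential in the free count)."""
        free = [i for i, v in enumerate(self.values) if v is None]
        base = sum(v << i for i, v in enumerate(self.values) if v)
        for bits in range(1 << len(free)):
            yield base | sum(((bits >> j) & 1) << i for j, i in enumerate(free))

    def __str__(self) -> str:
        return "".join("*" if v is None else str(v) for v in self.values)

    def __repr__(self) -> str:
        return f"Subspace({self})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Subspace) and self.values == other.values

    def __lt__(self, other) -> bool:
        key = tuple(2 if v is None else v for v in self.values)
        okey = tuple(2 if v is None else v for v in other.values)
        return key < okey

    def __hash__(self) -> int:
        return hash(self.values)


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attractor:
    """A terminal strongly connected component of the STG."""

    states: tuple[int, ...]
    scheme: str
    oscillating: tuple[str, ...]

    @property
    def kind(self) -> str:
        return "point" if len(self.states) == 1 else "complex"

    @property
    def min_state(self) -> int:
        return self.states[0]

    def state_strings(self, n: int) -> list[str]:
        return [state_to_str(s, n) for s in self.states]


@dataclass
class MAAReport:
    """A motif-avoidant attractor with its trap-space context and metrics.

    ``metrics`` maps each avoided minimal trap space to ``(M, d, m)``:
    M = free-variable count of the smallest trap space containing both the
    attractor and that minimal trap space, d = number of oscillating
    variables, m = minimal disagreement of an attractor state with the trap
    space's fixed values, restricted to the oscillating variables.
    """

    attractor: Attractor
    enclosing_subspace: Subspace
    enclosing_trap_space: Subspace
    is_motif_avoidant: bool
    metrics: dict[Subspace, tuple[int, int, int]] = field(default_factory=dict)

    def best_metrics(self) -> tuple[int, int, int]:
        """The (M, d, m) triple minimizing the induced delay bound.

        The bound formula is evaluated directly here because reports can
        carry degenerate triples (m = 0 when an attractor state agrees with
        the trap space on every oscillating variable) that the validated
        bound function rejects.
        """
        return min(self.metrics.values(),
                   key=lambda t: (t[0] - t[1]) * (t[0] - 1) + t[2] * (t[2] + 1) // 2)


def _check_size(net: BooleanNetwork, limit: int = STG_VARIABLE_LIMIT) -> None:
    if net.n > limit:
        raise SizeGuardError(
            f"network has {net.n} variables; explicit analysis is limited to {limit}")


def _async_successors(net: BooleanNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Asynchronous transitions as (sources, targets) arrays (changes only)."""
    n = net.n
    vals = net.values_on_all_states()
    states = np.arange(1 << n, dtype=np.int64)
    rows, cols = [], []
    for i in range(n):
        cur = (states >> i) & 1
        changed = vals[:, i] != cur
        rows.append(states[changed])
        cols.append(states[changed] ^ (1 << i))
    return np.concatenate(rows), np.concatenate(cols)


def _sync_successors(net: BooleanNetwork) -> np.ndarray:
    n = net.n
    vals = net.values_on_all_states()
    succ = np.zeros(1 << n, dtype=np.int64)
    for i in range(n):
        succ |= vals[:, i].astype(np.int64) << i
    return succ


def build_stg(net: BooleanNetwork, scheme: str = "asynchronous") -> nx.DiGraph:
    """Explicit state transition graph with string-labelled states.

    Asynchronous: one edge per single-variable update that changes the state
    (non-changing self-transitions are omitted; fixed points have out-degree
    zero).  Synchronous: exactly one successor per state (possibly itself).
    """
    _check_size(net)
    n = net.n
    g = nx.DiGraph()
    g.add_nodes_from(state_to_str(s, n) for s in range(1 << n))
    if scheme == "asynchronous":
        rows, cols = _async_successors(net)
        g.add_edges_from((state_to_str(int(s), n), state_to_str(int(t), n))
                         for s, t in zip(rows, cols))
    elif scheme == "synchronous":
        succ = _sync_successors(net)
        g.add_edges_from((state_to_str(s, n), state_to_str(int(succ[s]), n))
                         for s in range(1 << n))
    else:
        raise ValueError(f"unknown update scheme {scheme!r}")
    return g


def attractors(net: BooleanNetwork, scheme: str = "asynchronous") -> list[Attractor]:
    """Terminal strongly connected components of the STG, sorted by their
    lexicographically smallest member state."""
    _check_size(net)
    n = net.n
    if n == 0:
        return []
    if scheme == "asynchronous":
        rows, cols = _async_successors(net)
    elif scheme == "synchronous":
        succ = _sync_successors(net)
        rows = np.arange(1 << n, dtype=np.int64)
        keep = succ != rows
        rows, cols = rows[keep], succ[keep]
    else:
        raise ValueError(f"unknown update scheme {scheme!r}")
    size = 1 << n
    graph = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                       shape=(size, size))
    ncomp, labels = connected_components(graph, directed=True, connection="strong")
    terminal = np.ones(ncomp, dtype=bool)
    escaping = labels[rows] != labels[cols]
    terminal[labels[rows[escaping]]] = False
    out: list[Attractor] = []
    term_labels = np.nonzero(terminal)[0]
    states_by_label: dict[int, list[int]] = {int(lb): [] for lb in term_labels}
    for s in np.nonzero(terminal[labels])[0]:
        states_by_label[int(labels[s])].append(int(s))
    for lb, sts in states_by_label.items():
        sts = sorted(sts)
        osc_mask = 0
        for s in sts[1:]:
            osc_mask |= s ^ sts[0]
        osc = tuple(net.variables[i] for i in range(n) if (osc_mask >> i) & 1)
        out.append(Attractor(states=tuple(sts), scheme=scheme, oscillating=osc))
    out.sort(key=lambda a: a.min_state)
    return out


# ---------------------------------------------------------------------------
# Trap spaces
# ---------------------------------------------------------------------------

def _restricted_values(net: BooleanNetwork, v: str, fixed: dict[int, int]
                       ) -> tuple[np.ndarray, list[int]]:
    """Values of ``f_v`` over the cube of its inputs *not* fixed by ``fixed``.

    Returns ``(values, free_input_indices)`` where ``values[b]`` is the output
    for the free-input assignment with bits ``b`` (free inputs in function
    input order, first free input = least significant bit).
    """
    inputs, table = net.functions[v]
    base = 0
    free: list[int] = []
    free_pos: list[int] = []
    for j, u in enumerate(inputs):
        ui = net.index(u)
        if ui in fixed:
            base |= fixed[ui] << j
        else:
            free.append(ui)
            free_pos.append(j)
    f = len(free)
    idx = np.full(1 << f, base, dtype=np.int64)
    if f:
        assign = np.arange(1 << f, dtype=np.int64)
        for b, j in enumerate(free_pos):
            idx |= ((assign >> b) & 1) << j
    return table[idx], free


def is_trap_space(net: BooleanNetwork, sub: Subspace) -> bool:
    """True iff no trajectory can leave the subspace.

    Checked on the update functions directly: every fixed variable's function,
    restricted to the subspace, must be constantly the fixed value.
    """
    fixed = sub.fixed
    for i, b in fixed.items():
        vals, _ = _restricted_values(net, net.variables[i], fixed)
        if not np.all(vals == b):
            return False
    return True


def smallest_enclosing_trap_space(net: BooleanNetwork, states=None,
                                  seed: Subspace | None = None) -> Subspace:
    """The unique inclusion-smallest trap space containing the given states
    (or containing the seed subspace).

    Starts from the componentwise span and repeatedly frees any fixed
    variable whose function violates the fixed value somewhere in the current
    subspace; trap spaces are intersection-closed, so the fixpoint is the
    smallest enclosing trap space.
    """
    n = net.n
    if seed is not None:
        values = list(seed.values)
    else:
        states = list(states)
        if not states:
            raise ValueError("state set must be nonempty")
        ones = states[0]
        zeros = ~states[0]
        for s in states[1:]:
            ones &= s
            zeros &= ~s
        values = [1 if (ones >> i) & 1 else (0 if (zeros >> i) & 1 else None)
                  for i in range(n)]
    changed = True
    while changed:
        changed = False
        fixed = {i: v for i, v in enumerate(values) if v is not None}
        for i, b in list(fixed.items()):
            vals, _ = _restricted_values(net, net.variables[i], fixed)
            if not np.all(vals == b):
                values[i] = None
                changed = True
    return Subspace(values)


def _completable(net: BooleanNetwork, w: int, b: int, cur: list,
                 decided: list[bool]) -> bool:
    """Can the partial assignment still be extended so that f_w == b holds on
    the final subspace?

    ``cur`` holds the fixed values (None = free or undecided); ``decided[i]``
    marks variables whose final status (fixed value or free) is known.  The
    condition is: there is an assignment of the undecided inputs under which
    f_w, with decided-fixed inputs substituted, is constantly ``b`` over the
    decided-free inputs.  (Fixing every undecided input is optimal, so this
    is exact, and it is the final constancy check once everything is decided.)
    """
    name = net.variables[w]
    inputs, _ = net.functions[name]
    fixed = {}
    for u in inputs:
        ui = net.index(u)
        if cur[ui] is not None:
            fixed[ui] = cur[ui]
    vals, free = _restricted_values(net, name, fixed)
    if not free:
        return bool(np.all(vals == b))
    starred_axes = [j for j, ui in enumerate(free) if decided[ui]]
    undecided_axes = [j for j, ui in enumerate(free) if not decided[ui]]
    if not undecided_axes:
        return bool(np.all(vals == b))
    if not starred_axes:
        return bool(np.any(vals == b))
    f = len(free)
    cube = vals.reshape((2,) * f)  # axis a <-> free input f-1-a
    axes = [f - 1 - j for j in reversed(undecided_axes)] + \
           [f - 1 - j for j in reversed(starred_axes)]
    arr = np.transpose(cube, axes=axes).reshape(1 << len(undecided_axes),
                                                1 << len(starred_axes))
    return bool(np.any(np.all(arr == b, axis=1)))


def _trap_spaces_dfs(net: BooleanNetwork, within: Subspace | None = None,
                     proper: bool = False, first_only: bool = False
                     ) -> list[Subspace]:
    """All trap spaces refining ``within`` (which must itself be a trap space
    when given), found by depth-first branching over partial assignments.

    With ``proper=True`` only subspaces fixing at least one of ``within``'s
    free variables are reported; ``first_only`` stops at the first hit.
    """
    n = net.n
    if within is None:
        within = Subspace.full(n)
    free_vars = [i for i, v in enumerate(within.values) if v is None]
    if len(free_vars) > BRANCHING_VARIABLE_LIMIT:
        raise CapacityError(
            f"{len(free_vars)} free variables exceed the branching engine "
            f"capacity of {BRANCHING_VARIABLE_LIMIT}")
    cur = list(within.values)
    decided = [v is not None for v in within.values]
    # free variables of `within` whose function depends on variable i
    dependents: dict[int, list[int]] = {i: [] for i in range(n)}
    for w in free_vars:
        for u in net.inputs(net.variables[w]):
            dependents[net.index(u)].append(w)
    results: list[Subspace] = []

    def rec(depth: int, assigned_any: bool) -> bool:
        if depth == len(free_vars):
            if not proper or assigned_any:
                results.append(Subspace(cur))
                return first_only
            return False
        i = free_vars[depth]
        for choice in (0, 1, None):
            cur[i] = choice
            decided[i] = True
            ok = True
            if choice is not None and not _completable(net, i, choice, cur, decided):
                ok = False
            if ok:
                for w in dependents[i]:
                    if w != i and cur[w] is not None and decided[w]:
                        if not _completable(net, w, cur[w], cur, decided):
                            ok = False
                            break
            if ok and rec(depth + 1, assigned_any or choice is not None):
                cur[i] = None
                decided[i] = False
                return True
            cur[i] = None
        decided[i] = False
        return False

    rec(0, False)
    return results


def _filter_minimal(subs: list[Subspace]) -> list[Subspace]:
    minimal = []
    for s in subs:
        if not any(t is not s and t != s and s.contains_subspace(t) for t in subs):
            minimal.append(s)
    return sorted(minimal)


def minimal_trap_spaces(net: BooleanNetwork, engine: str = "branching"
                        ) -> list[Subspace]:
    """All inclusion-minimal trap spaces.

    If the network has no proper trap space, the full space (itself always a
    trap space) is the unique minimal trap space.
    """
    if engine == "branching":
        return _filter_minimal(_trap_spaces_dfs(net))
    if engine == "brute":
        if net.n > BRUTE_FORCE_LIMIT:
            raise CapacityError(
                f"brute-force engine is limited to {BRUTE_FORCE_LIMIT} variables")
        subs = [s for s in (Subspace(v) for v in product((0, 1, None), repeat=net.n))
                if is_trap_space(net, s)]
        return _filter_minimal(subs)
    raise ValueError(f"unknown engine {engine!r}")


def is_minimal_trap_space(net: BooleanNetwork, sub: Subspace) -> bool:
    """True iff ``sub`` is a trap space containing no proper sub-trap-space."""
    if not is_trap_space(net, sub):
        return False
    return not _trap_spaces_dfs(net, within=sub, proper=True, first_only=True)


# ---------------------------------------------------------------------------
# Motif avoidance
# ---------------------------------------------------------------------------

def _span(states, n: int) -> Subspace:
    states = list(states)
    ones = states[0]
    zeros = ~states[0]
    for s in states[1:]:
        ones &= s
        zeros &= ~s
    return Subspace(1 if (ones >> i) & 1 else (0 if (zeros >> i) & 1 else None)
                    for i in range(n))


def find_maas(net: BooleanNetwork, include_metrics: bool = True) -> list[MAAReport]:
    """Motif-avoidant attractors under asynchronous update.

    A complex attractor is motif-avoidant iff its smallest enclosing trap
    space is not a minimal trap space (equivalently: its states lie in no
    minimal trap space).  Reports are ordered by smallest attractor state and
    carry the (M, d, m) metrics for every avoided minimal trap space when
    ``include_metrics`` is set.
    """
    reports: list[MAAReport] = []
    mts: list[Subspace] | None = None
    for att in attractors(net, "asynchronous"):
        if att.kind != "complex":
            continue
        span = _span(att.states, net.n)
        enclosing = smallest_enclosing_trap_space(net, seed=span)
        if not _trap_spaces_dfs(net, within=enclosing, proper=True, first_only=True):
            continue  # enclosing trap space is minimal: a regular attractor
        report = MAAReport(attractor=att, enclosing_subspace=span,
                           enclosing_trap_space=enclosing, is_motif_avoidant=True)
        if include_metrics:
            if mts is None:
                mts = minimal_trap_spaces(net)
            for tmin in mts:
                report.metrics[tmin] = maa_metrics(net, report, tmin, validate=False)
        reports.append(report)
    return reports


def has_maa(net: BooleanNetwork) -> bool:
    """Whether the network has at least one motif-avoidant attractor."""
    if net.n == 0:
        return False
    for att in attractors(net, "asynchronous"):
        if att.kind != "complex":
            continue
        enclosing = smallest_enclosing_trap_space(net, seed=_span(att.states, net.n))
        if _trap_spaces_dfs(net, within=enclosing, proper=True, first_only=True):
            return True
    return False


def maa_metrics(net: BooleanNetwork, report: MAAReport, tmin: Subspace,
                validate: bool = True) -> tuple[int, int, int]:
    """(M, d, m) for one motif-avoidant attractor and one avoided minimal
    trap space.

    M is the free-variable count of the smallest trap space containing both
    the attractor and ``tmin``; d is the number of oscillating variables of
    the attractor; m is the minimal Hamming disagreement of an attractor
    state with ``tmin``'s fixed values, restricted to oscillating variables.
    """
    att = report.attractor
    if att.kind != "complex":
        raise ValueError("metrics are defined for complex attractors only")
    if validate:
        if not is_minimal_trap_space(net, tmin):
            raise ValueError(f"{tmin} is not a minimal trap space")
        if any(tmin.contains_state(s) for s in att.states):
            raise ValueError(f"{tmin} intersects the attractor")
    # span of (attractor union tmin): variables fixed to the same value in both
    span = report.enclosing_subspace
    union_values = [span.values[i]
                    if span.values[i] is not None and span.values[i] == tmin.values[i]
                    else None
                    for i in range(net.n)]
    enclosing = smallest_enclosing_trap_space(net, seed=Subspace(union_values))
    M = enclosing.free_count
    d = len(att.oscillating)
    osc_idx = [net.index(v) for v in att.oscillating]
    m = min(sum(1 for i in osc_idx
                if tmin.values[i] is not None and (s >> i) & 1 != tmin.values[i])
            for s in att.states)
    return M, d, m
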