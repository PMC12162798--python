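"""Linear (delay) extensions of interaction-graph edges.

Extending an edge ``u -> v`` inserts a fresh variable that copies ``u`` and
replaces ``u`` in the update function of ``v``.  The new node acts as a
one-step memory of its parent: states where every delay node agrees with its
parent are *canonical*, the rest are *memory* states.  Memory states can gain
transitions the original system lacked, which is the mechanism by which a
delay can let the states of a motif-avoidant attractor reach an avoided trap
space, destroying the attractor.  Extending every edge makes the interaction
graph L-cuttable and eliminates all motif avoidance; this module also
provides the exhaustive search for the minimal number of delays and the
closed-form bounds on that number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from .dynamics import (MAAReport, SizeGuardError, STG_VARIABLE_LIMIT,
                       find_maas, has_maa)
from .network import BooleanNetwork

__all__ = [
    "delay_name",
    "linear_extend",
    "single_delay_survey",
    "minimal_delay_set_size",
    "DelayLimitError",
    "delay_upper_bound",
    "worst_case_bound",
    "MemoryTransitionReport",
    "classify_memory_transitions",
    "projected_stg",
]


def delay_name(u: str, v: str) -> str:
    """Canonical name of the delay variable on edge u -> v."""
    return f"d_{u}_{v}"


def _essential_edges(net: BooleanNetwork) -> list[tuple[str, str]]:
    edges = [(u, v) for v in net.variables for u in net.inputs(v)]
    return sorted(edges, key=lambda e: (net.index(e[0]), net.index(e[1])))


def linear_extend(net: BooleanNetwork, delays) -> BooleanNetwork:
    """Extend each edge ``(u, v)`` in ``delays`` with one delay node.

    Variable order of the result: original variables first, then delay nodes
    in edge-sorted order.  Deleting the delay nodes recovers the original
    network exactly.
    """
    delays = list(delays)
    if len(set(delays)) != len(delays):
        raise ValueError("duplicate edge in delay set")
    for u, v in delays:
        if u not in net.functions or v not in net.functions:
            raise ValueError(f"edge ({u!r}, {v!r}) references unknown variables")
        if u not in net.inputs(v):
            raise ValueError(f"({u!r}, {v!r}) is not an essential edge")
    delays = sorted(delays, key=lambda e: (net.index(e[0]), net.index(e[1])))
    names = {e: delay_name(*e) for e in delays}
    for name in names.values():
        if name in net.functions:
            raise ValueError(f"delay name {name!r} collides with a variable")
    replacements: dict[str, dict[str, str]] = {}
    for (u, v), z in names.items():
        replacements.setdefault(v, {})[u] = z
    functions: dict[str, tuple] = {}
    for w in net.variables:
        inputs, table = net.function(w)
        subst = replacements.get(w, {})
        functions[w] = (tuple(subst.get(u, u) for u in inputs), table)
    for (u, v), z in names.items():
        functions[z] = ((u,), np.array([0, 1], dtype=np.uint8))
    variables = list(net.variables) + [names[e] for e in delays]
    return BooleanNetwork(functions, variables=variables)


def single_delay_survey(net: BooleanNetwork, report: MAAReport
                        ) -> tuple[dict[tuple[str, str], bool], int]:
    """Try one delay on each incoming edge of each oscillating variable.

    Each delay is considered separately; an edge *succeeds* when the extended
    network has no motif-avoidant attractor at all.  Returns the per-edge
    verdict map and the count of successful edges.
    """
    if not report.is_motif_avoidant:
        raise ValueError("the report does not describe a motif-avoidant attractor")
    osc = set(report.attractor.oscillating)
    edges = sorted({(u, v) for v in osc for u in net.inputs(v)},
                   key=lambda e: (net.index(e[0]), net.index(e[1])))
    verdicts: dict[tuple[str, str], bool] = {}
    for edge in edges:
        extended = linear_extend(net, [edge])
        if extended.n > STG_VARIABLE_LIMIT:
            raise SizeGuardError(
                f"extended network has {extended.n} variables")
        verdicts[edge] = not has_maa(extended)
    return verdicts, sum(verdicts.values())


class DelayLimitError(RuntimeError):
    """Exhaustive delay search ran out of budget; carries the lower bound."""

    def __init__(self, lower_bound: int):
        super().__init__(
            f"no delay set of size <= {lower_bound - 1} eliminates the attractor; "
            f"the minimum is at least {lower_bound}")
        self.lower_bound = lower_bound


def minimal_delay_set_size(net: BooleanNetwork, limit: int | None = None
                           ) -> tuple[int, tuple[tuple[str, str], ...]]:
    """Smallest number of single-edge delays whose joint extension leaves the
    network free of motif-avoidant attractors, by exhaustive subset search.

    Requires a network with exactly one motif-avoidant attractor.  Subsets
    are enumerated by increasing cardinality (then lexicographic edge order),
    so sufficiency comes with a necessity certificate: all smaller subsets
    were verified to fail.  Raises :class:`DelayLimitError` with the implied
    lower bound when ``limit`` is exhausted.
    """
    maas = find_maas(net, include_metrics=False)
    if len(maas) != 1:
        raise ValueError(f"expected exactly one motif-avoidant attractor, "
                         f"found {len(maas)}")
    edges = _essential_edges(net)
    if limit is None:
        limit = len(edges)
    for k in range(1, limit + 1):
        for subset in combinations(edges, k):
            extended = linear_extend(net, subset)
            if extended.n > STG_VARIABLE_LIMIT:
                raise SizeGuardError(
                    f"extended network has {extended.n} variables")
            if not has_maa(extended):
                return k, subset
    raise DelayLimitError(limit + 1)


def delay_upper_bound(M: int, d: int, m: int) -> int:
    """Upper bound (M - d)(M - 1) + m(m + 1)/2 on the number of delays needed
    to eliminate a motif-avoidant attractor.

    M is the free-variable count of the smallest trap space containing the
    attractor and the avoided minimal trap space, d the number of oscillating
    variables, m the minimal restricted disagreement with the trap space.
    """
    if not (2 <= d <= M):
        raise ValueError(f"need 2 <= d <= M, got d={d}, M={M}")
    if not (1 <= m < d):
        raise ValueError(f"need 1 <= m < d, got m={m}, d={d}")
    return (M - d) * (M - 1) + m * (m + 1) // 2


def worst_case_bound(e_max: int, d: int) -> float:
    """Worst-case form of the delay bound for a complete interaction graph
    with ``e_max = N**2`` edges and maximal disagreement ``m = d - 1``:
    ``e_max - (sqrt(e_max) - d/2)(d + 1)``, strictly below ``e_max``."""
    n = math.isqrt(e_max)
    if n * n != e_max:
        raise ValueError(f"e_max={e_max} is not a perfect square")
    if not (2 <= d <= n):
        raise ValueError(f"need 2 <= d <= sqrt(e_max), got d={d}")
    return e_max - (n - d / 2) * (d + 1)


# ---------------------------------------------------------------------------
# Memory states and projected STGs
# ---------------------------------------------------------------------------

def _delay_layout(net: BooleanNetwork, extended: BooleanNetwork):
    """Indices of original variables and (delay, parent) pairs in ``extended``."""
    originals = [extended.index(v) for v in net.variables]
    pairs = []
    for z in extended.variables:
        if z in net.functions:
            continue
        (parent,), _ = extended.function(z)
        pairs.append((extended.index(z), extended.index(parent)))
    return originals, pairs


def _project(state: int, originals: list[int]) -> int:
    out = 0
    for b, i in enumerate(originals):
        out |= ((state >> i) & 1) << b
    return out


def _is_canonical(state: int, pairs) -> bool:
    return all((state >> z) & 1 == (state >> p) & 1 for z, p in pairs)


@dataclass
class MemoryTransitionReport:
    """Transitions of memory states that differ from the original system.

    ``gained``/``lost`` list ``(memory_state, variable, projected_source,
    projected_target)`` in the extended network's state encoding; only
    updates of original variables are compared.
    """

    gained: list[tuple[int, str, int, int]] = field(default_factory=list)
    lost: list[tuple[int, str, int, int]] = field(default_factory=list)


def classify_memory_transitions(net: BooleanNetwork, delays=None,
                                extended: BooleanNetwork | None = None
                                ) -> MemoryTransitionReport:
    """Compare each memory state's transitions (on original variables) with
    the transitions of its projection in the original system.

    ``extended`` may be supplied directly (any network whose extra variables
    each copy one original variable), e.g. to analyse a non-functional delay
    node that the target does not actually read.
    """
    if extended is None:
        extended = linear_extend(net, delays)
    if extended.n > STG_VARIABLE_LIMIT:
        raise SizeGuardError(f"extended network has {extended.n} variables")
    originals, pairs = _delay_layout(net, extended)
    vals_ext = extended.values_on_all_states()
    vals_orig = net.values_on_all_states()
    report = MemoryTransitionReport()
    for s in range(1 << extended.n):
        if _is_canonical(s, pairs):
            continue
        proj = _project(s, originals)
        for b, name in enumerate(net.variables):
            i = originals[b]
            cur = (s >> i) & 1
            ext_changes = vals_ext[s, i] != cur
            orig_changes = vals_orig[proj, net.index(name)] != cur
            if ext_changes and not orig_changes:
                report.gained.append((s, name, proj, proj ^ (1 << b)))
            elif orig_changes and not ext_changes:
                report.lost.append((s, name, proj, proj ^ (1 << b)))
    return report


@dataclass
class ProjectedSTG:
    """Projection of a delay-extended STG back onto the original states.

    ``graph`` is a digraph on original state integers; each edge carries
    ``kind`` ("original" or "gained") and, for gained edges, one ``witness``
    path of extended states through memory-state interiors.
    """

    graph: nx.DiGraph
    n: int

    def gained_edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u, v, d in self.graph.edges(data=True)
                if d["kind"] == "gained"]


def projected_stg(net: BooleanNetwork, delays) -> ProjectedSTG:
    """Project the extended STG: original states are joined by an edge when
    the corresponding canonical states are connected by a path through
    memory states only (no intermediate canonical state); self-edges are
    excluded.  Every edge of the original asynchronous STG is retained."""
    extended = linear_extend(net, delays)
    if extended.n > STG_VARIABLE_LIMIT:
        raise SizeGuardError(f"extended network has {extended.n} variables")
    originals, pairs = _delay_layout(net, extended)
    n_ext = extended.n
    vals = extended.values_on_all_states()

    def successors(s: int):
        for i in range(n_ext):
            if vals[s, i] != (s >> i) & 1:
                yield s ^ (1 << i)

    from .dynamics import _async_successors
    orig_edges = set(zip(*map(lambda a: a.tolist(), _async_successors(net))))

    g = nx.DiGraph()
    g.add_nodes_from(range(1 << net.n))
    for c in range(1 << n_ext):
        if not _is_canonical(c, pairs):
            continue
        src = _project(c, originals)
        parent: dict[int, int] = {}
        queue = [c]
        seen = {c}
        while queue:
            x = queue.pop(0)
            for y in successors(x):
                if y in seen:
                    continue
                seen.add(y)
                parent[y] = x
                if _is_canonical(y, pairs):
                    dst = _project(y, originals)
                    if dst != src and not g.has_edge(src, dst):
                        path = [y]
                        node = y
                        while node != c:
                            node = parent[node]
                            path.append(node)
                        path.reverse()
                        kind = "original" if (src, dst) in orig_edges else "gained"
                        g.add_edge(src, dst, kind=kind,
                                   witness=path if kind == "gained" else None)
                    continue  # do not expand past a canonical state
                queue.append(y)
    return ProjectedSTG(graph=g, n=net.n)
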