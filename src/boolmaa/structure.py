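"""Interaction-graph criteria that rule motif-avoidant attractors out.

Under asynchronous update, sustained oscillation requires a non-positive
cycle (edge-sign product -1, or a cycle containing an ambiguous edge), and a
non-trivial minimal trap space requires a non-negative cycle.  A network
whose interaction graph has no cycle, only positive cycles, only negative
cycles, or no path from a non-positive cycle to a non-negative cycle
therefore cannot have a motif-avoidant attractor.  Neither can a network
whose interaction graph admits a *linear cut*: a linear node (in- and
out-degree one) on every cycle and on every edge-path from a branching node
to a merging node — in such networks attractors and minimal trap spaces are
in bijection.

Sign conventions: ambiguous (sign 0) edges count as both positive and
negative, so a cycle containing one is both non-negative and non-positive.

Detection notes.  Non-positive cycles are decided exactly by the
parity-doubled graph: an odd closed walk decomposes into simple cycles of
parities summing odd, so one of them is odd.  The same argument fails for
even walks (two odd cycles through a vertex give an even walk), and exact
even-cycle detection is a famously hard problem; non-negative cycles and
the cycle-vertex sets for the path criterion are therefore taken from
explicit simple-cycle enumeration with a budget.  If the budget is
exhausted before the flags saturate, the unresolved answers fall back to
the conservative side (cycle assumed present), which can only make the
exclusion verdict less aggressive, never unsound.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = [
    "CycleSignSummary",
    "cycle_sign_summary",
    "has_nonpositive_cycle_parity",
    "is_l_cuttable",
    "maa_excluded_by_structure",
]

#: Simple-cycle enumeration budget for cycle_sign_summary.
DEFAULT_CYCLE_BUDGET = 100_000


@dataclass(frozen=True)
class CycleSignSummary:
    """Cycle-sign facts about a signed digraph.

    ``nonnegative`` means sign product +1 or an ambiguous (0) edge on the
    cycle; ``nonpositive`` means sign product -1 or an ambiguous edge.
    """

    has_cycle: bool
    has_nonnegative_cycle: bool
    has_nonpositive_cycle: bool
    path_nonpos_to_nonneg: bool
    exact: bool = True


def _parity_graph(ig: nx.DiGraph) -> nx.DiGraph:
    """Parity-doubled graph: node (v, p) tracks the sign parity of a walk.

    A positive edge preserves parity, a negative edge flips it, and an
    ambiguous edge does both (it may be counted with either sign).
    """
    pg = nx.DiGraph()
    for v in ig.nodes:
        pg.add_node((v, 0))
        pg.add_node((v, 1))
    for u, v, data in ig.edges(data=True):
        sign = data.get("sign", 1)
        for p in (0, 1):
            if sign in (1, 0):
                pg.add_edge((u, p), (v, p))
            if sign in (-1, 0):
                pg.add_edge((u, p), (v, 1 - p))
    return pg


def has_nonpositive_cycle_parity(ig: nx.DiGraph) -> bool:
    """Exact non-positive-cycle test via the parity-doubled graph.

    There is a simple cycle with an odd number of negative edges (ambiguous
    edges counting as either sign) iff some (v, 0) reaches (v, 1).
    """
    pg = _parity_graph(ig)
    for v in ig.nodes:
        if nx.has_path(pg, (v, 0), (v, 1)):
            return True
    return False


def _on_cycle_vertices(ig: nx.DiGraph) -> set:
    """Vertices lying on some cycle (a nontrivial SCC or a self-loop)."""
    out = set()
    for scc in nx.strongly_connected_components(ig):
        if len(scc) > 1:
            out |= scc
    out |= {v for v in ig.nodes if ig.has_edge(v, v)}
    return out


def _reaches(ig: nx.DiGraph, sources: set, targets: set) -> bool:
    if sources & targets:
        return True
    seen = set(sources)
    stack = list(sources)
    while stack:
        v = stack.pop()
        for w in ig.successors(v):
            if w in targets:
                return True
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def cycle_sign_summary(ig: nx.DiGraph,
                       max_cycles: int = DEFAULT_CYCLE_BUDGET) -> CycleSignSummary:
    """Cycle-sign flags and the non-positive-to-non-negative path flag.

    Simple cycles are enumerated (stopping early once every flag is settled
    affirmatively); the non-positive flag is additionally cross-computed by
    the exact parity-graph test, which also decides it when enumeration is
    cut short by the budget.
    """
    on_cycle = _on_cycle_vertices(ig)
    if not on_cycle:
        return CycleSignSummary(False, False, False, False)
    nonpos_flag = has_nonpositive_cycle_parity(ig)
    nonneg_v: set = set()
    nonpos_v: set = set()
    path = False
    exhausted = True
    count = 0
    for cycle in nx.simple_cycles(ig):
        count += 1
        signs = [ig.edges[cycle[i], cycle[(i + 1) % len(cycle)]].get("sign", 1)
                 for i in range(len(cycle))]
        ambiguous = any(s == 0 for s in signs)
        negative_count = sum(1 for s in signs if s == -1)
        if ambiguous or negative_count % 2 == 0:
            nonneg_v.update(cycle)
        if ambiguous or negative_count % 2 == 1:
            nonpos_v.update(cycle)
        if not path and nonpos_v and nonneg_v and _reaches(ig, nonpos_v, nonneg_v):
            path = True
        if path and nonneg_v and nonpos_v:
            exhausted = False  # saturated early; remaining cycles add nothing
            break
        if count >= max_cycles:
            # Unresolved absences fall back to "present" (conservative for
            # the exclusion verdict); vertex sets are over-approximated.
            return CycleSignSummary(
                has_cycle=True,
                has_nonnegative_cycle=True,
                has_nonpositive_cycle=nonpos_flag,
                path_nonpos_to_nonneg=bool(nonpos_flag) and _reaches(
                    ig, nonpos_v or on_cycle, nonneg_v or on_cycle),
                exact=False,
            )
    return CycleSignSummary(
        has_cycle=True,
        has_nonnegative_cycle=bool(nonneg_v),
        has_nonpositive_cycle=nonpos_flag if not exhausted else bool(nonpos_v),
        path_nonpos_to_nonneg=path,
    )


def is_l_cuttable(ig: nx.DiGraph) -> bool:
    """Whether the digraph admits a linear cut (signs are ignored).

    A linear node has in-degree and out-degree exactly one.  The graph is
    L-cuttable iff after removing all linear nodes the remainder is acyclic
    and no remaining path of at least one edge connects a node with
    out-degree >= 2 to a node with in-degree >= 2 (degrees measured in the
    original graph).  Paths of zero length do not count: a node that both
    branches and merges is harmless as long as every edge-path through it is
    cut, which is what makes the full linear extension of any graph
    L-cuttable.
    """
    linear = {v for v in ig.nodes
              if ig.in_degree(v) == 1 and ig.out_degree(v) == 1}
    rest = ig.subgraph([v for v in ig.nodes if v not in linear])
    if not nx.is_directed_acyclic_graph(rest):
        return False
    branching = {v for v in rest.nodes if ig.out_degree(v) >= 2}
    merging = {v for v in rest.nodes if ig.in_degree(v) >= 2}
    for v in branching:
        reach = nx.descendants(rest, v)
        if reach & merging:
            return False
    return True


def maa_excluded_by_structure(ig: nx.DiGraph) -> tuple[bool, str | None]:
    """Decide whether the interaction graph alone rules out motif-avoidant
    attractors; returns (excluded, reason) with the first satisfied
    criterion."""
    summary = cycle_sign_summary(ig)
    if not summary.has_cycle:
        return True, "no cycle"
    if not summary.has_nonpositive_cycle:
        return True, "only positive cycles"
    if not summary.has_nonnegative_cycle:
        return True, "only negative cycles"
    if not summary.path_nonpos_to_nonneg:
        return True, "no path from a non-positive cycle to a non-negative cycle"
    if is_l_cuttable(ig):
        return True, "L-cuttable"
    return False, None
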