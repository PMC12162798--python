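"""Node-deletion reduction and constant percolation.

A variable without an (essential) self-input can be deleted by substituting
its update function into the functions of its targets; the reduced system
preserves all point attractors, and every reduced transition corresponds to
at least one transition of the original system.  Repeating the deletion
while self-regulation-free variables exist yields a *maximally reduced*
network in which every remaining variable self-regulates (or the empty
network).  Substitution can silently simplify logic (e.g. ``X | !X == 1``),
which is how reduction both creates and destroys motif-avoidant attractors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import BooleanNetwork, MAX_INPUTS

__all__ = [
    "ReductionGuardError",
    "ReductionTrace",
    "delete_node",
    "reduce_max",
    "percolate",
]


class ReductionGuardError(RuntimeError):
    """A substitution would exceed the per-function input guard."""


@dataclass
class ReductionTrace:
    """Record of a maximal reduction: deletion order and the final network."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    final: BooleanNetwork | None = None
    skipped: bool = False


def delete_node(net: BooleanNetwork, v: str,
                max_inputs: int = MAX_INPUTS) -> BooleanNetwork:
    """Delete a non-self-regulating variable by substituting its function
    into every function that reads it.

    The resulting functions are re-normalized, so substitution-created
    identities (e.g. a clause becoming ``X & !X``) are simplified away; this
    is the mechanism by which reduction can fix variables and trap formerly
    motif-avoidant oscillations.
    """
    inputs_v, table_v = net.function(v)
    if v in inputs_v:
        raise ValueError(f"{v!r} has an essential self-input and cannot be deleted")
    new_functions: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for w in net.variables:
        if w == v:
            continue
        inputs_w, table_w = net.function(w)
        if v not in inputs_w:
            new_functions[w] = (inputs_w, table_w)
            continue
        merged = [u for u in inputs_w if u != v]
        merged += [u for u in inputs_v if u not in merged]
        k = len(merged)
        if k > max_inputs:
            raise ReductionGuardError(
                f"substituting {v!r} into {w!r} needs {k} inputs (guard {max_inputs})")
        pos = {u: j for j, u in enumerate(merged)}
        assign = np.arange(1 << k, dtype=np.int64)
        idx_v = np.zeros(1 << k, dtype=np.int64)
        for j, u in enumerate(inputs_v):
            idx_v |= ((assign >> pos[u]) & 1) << j
        v_val = table_v[idx_v].astype(np.int64)
        idx_w = np.zeros(1 << k, dtype=np.int64)
        for j, u in enumerate(inputs_w):
            bit = v_val if u == v else (assign >> pos[u]) & 1
            idx_w |= bit << j
        new_functions[w] = (tuple(merged), table_w[idx_w])
    variables = [w for w in net.variables if w != v]
    return BooleanNetwork(new_functions, variables=variables)


def reduce_max(net: BooleanNetwork, max_inputs: int = MAX_INPUTS,
               allow_empty: bool = False) -> ReductionTrace:
    """Delete eligible variables until every remaining one self-regulates.

    Deletion policy: the eligible variable with the fewest essential inputs,
    ties broken by declaration order.  If a substitution trips the input
    guard the trace is marked ``skipped`` (and excluded from ensemble
    statistics by the callers).

    By default the endpoint retains at least one variable, mirroring
    model-manipulation tools that cannot represent an empty model: a lone
    constant variable regulates nothing, so there is no function to
    substitute it into.  Pass ``allow_empty=True`` to delete it anyway and
    reach the empty network.
    """
    trace = ReductionTrace()
    current = net
    while True:
        if current.n == 1 and not allow_empty:
            break
        eligible = [v for v in current.variables if not current.has_self_input(v)]
        if not eligible:
            break
        v = min(eligible, key=lambda u: (len(current.inputs(u)), current.index(u)))
        try:
            current = delete_node(current, v, max_inputs=max_inputs)
        except ReductionGuardError:
            trace.skipped = True
            break
        trace.steps.append((v, current.n))
    trace.final = current
    return trace


def percolate(net: BooleanNetwork, assignment: dict[str, int]) -> BooleanNetwork:
    """Fix variables to constants, propagate to a fixpoint, and remove every
    percolated variable.

    Functions that become constant once the assignment is substituted fix
    their own variable in turn.  Variables whose own function disagrees with
    the imposed value are still removed (the assignment conditions the
    dynamics); self-sustaining loops that are not forced by the assignment
    are left intact.  May return the empty network.
    """
    for u in assignment:
        if u not in net.functions:
            raise ValueError(f"unknown variable {u!r} in assignment")
    values = {u: int(b) for u, b in assignment.items()}
    changed = True
    while changed:
        changed = False
        for w in net.variables:
            if w in values:
                continue
            inputs_w, table_w = net.function(w)
            known = {j for j, u in enumerate(inputs_w) if u in values}
            if not known and len(table_w) > 1:
                continue
            base = 0
            free_pos = []
            for j, u in enumerate(inputs_w):
                if u in values:
                    base |= values[u] << j
                else:
                    free_pos.append(j)
            assign = np.arange(1 << len(free_pos), dtype=np.int64)
            idx = np.full(1 << len(free_pos), base, dtype=np.int64)
            for b, j in enumerate(free_pos):
                idx |= ((assign >> b) & 1) << j
            vals = table_w[idx]
            if np.all(vals == vals[0]):
                values[w] = int(vals[0])
                changed = True
    remaining = [w for w in net.variables if w not in values]
    new_functions = {}
    for w in remaining:
        inputs_w, table_w = net.function(w)
        base = 0
        free = []
        free_pos = []
        for j, u in enumerate(inputs_w):
            if u in values:
                base |= values[u] << j
            else:
                free.append(u)
                free_pos.append(j)
        assign = np.arange(1 << len(free_pos), dtype=np.int64)
        idx = np.full(1 << len(free_pos), base, dtype=np.int64)
        for b, j in enumerate(free_pos):
            idx |= ((assign >> b) & 1) << j
        new_functions[w] = (tuple(free), table_w[idx])
    return BooleanNetwork(new_functions, variables=remaining)
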