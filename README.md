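# boolmaa

Motif-avoidant attractors in asynchronous Boolean networks: detection,
structural exclusion, node-deletion reduction, delay (linear) extensions,
canalization measures, and critical N-K random-ensemble experiments.

## The problem

A Boolean network updates N binary variables by logic rules of their
regulators; under the *asynchronous* scheme one randomly chosen variable is
updated per step, and the long-term behaviours (attractors) are the terminal
strongly connected components of the state transition graph (STG).  A *trap
space* is a subspace `0*1*`-style hypercube that the dynamics cannot leave;
minimal trap spaces are the usual proxies for attractors in efficient
algorithms.  A **motif-avoidant attractor (MAA)** is a complex attractor
contained in no minimal trap space — it escapes every self-locking
configuration and breaks the trap-space/attractor correspondence those
algorithms rely on.  This package quantifies how rare MAAs are in random
critical networks, how node-deletion reduction creates (and destroys) them,
and how few delay nodes suffice to eliminate them.

Key objects and operations:

- `parse_bnet` / `write_bnet` — `.bnet` ("target, expression") I/O with
  semantic normalization (non-essential inputs pruned) and signed
  interaction-graph inference (`interaction_graph`).
- `attractors`, `minimal_trap_spaces`, `find_maas` — explicit-STG attractor
  detection (terminal SCCs), two interchangeable trap-space engines
  (branching DFS and a 3^N brute-force oracle), MAA classification with the
  `(M, d, m)` metrics: free variables of the joint enclosing trap space,
  oscillating-variable count, and minimal restricted Hamming disagreement
  with the avoided trap space.
- `maa_excluded_by_structure` — interaction-graph exclusion criteria: no
  cycle, only positive / only negative cycles, no path from a non-positive
  to a non-negative cycle, or an L-cuttable graph (linear node on every
  cycle and every branching-to-merging edge-path).
- `delete_node`, `reduce_max`, `percolate` — node-deletion reduction by
  function substitution.
- `linear_extend`, `single_delay_survey`, `minimal_delay_set_size`,
  `projected_stg`, `delay_upper_bound` — delay-node machinery, the
  exhaustive minimal-delay search, and the bound
  `(M - d)(M - 1) + m(m + 1)/2`.
- `sensitivity`, `effective_connectivity` — canalization measures on truth
  tables or expressions (prime-implicant based).
- `generate_critical_rbn`, `star_network`, `maa_frequency_experiment`,
  `reduction_experiment`, `fragility_experiment` — the critical N-K
  ensemble (`2Kp(1-p) = 1`) and the three desk-scale experiments, with
  Wilson-style 95% intervals.

## Worked example

```python
>>> import boolmaa as bm
>>> net = bm.parse_bnet("A, A & B | !A & !B\nB, A & B | !A & !B\n")
>>> [(a.kind, a.state_strings(net.n)) for a in bm.attractors(net)]
[('complex', ['00', '10', '01']), ('point', ['11'])]
>>> [str(t) for t in bm.minimal_trap_spaces(net)]
['11']
>>> report = bm.find_maas(net)[0]
>>> str(report.enclosing_trap_space), report.metrics[bm.Subspace.from_str("11")]
('**', (2, 2, 1))
>>> bm.single_delay_survey(net, report)[1]
4
```

This is the unique two-variable network with a motif-avoidant attractor
(both rules are XNOR).  The oscillation `{00, 01, 10}` is an attractor whose
smallest enclosing trap space is the whole state space, yet the minimal trap
space is the fixed point `11` — the attractor avoids it because reaching
`11` would need `A` updated before `B` *and* `B` before `A`.  The metrics
`(M, d, m) = (2, 2, 1)` say both variables oscillate and some attractor
state is one flip away from the trap space, so the single-delay bound is 1;
indeed all four possible single-edge delays destroy the MAA (the survey
reports 4 successes).

A command-line interface mirrors the library:

```sh
boolmaa analyze model.bnet          # attractors, trap spaces, MAA reports
boolmaa structure model.bnet        # cycle signs + exclusion verdict
boolmaa reduce model.bnet --max     # maximal node-deletion reduction
boolmaa mindelays model.bnet        # exhaustive minimal delay search
boolmaa canalization --expr "A | B & C"
boolmaa ensemble freq --N 10 --K 10 --samples 8000 --seed 1
```

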