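# Methods

This note records the models, conventions, parameter choices and known
limitations behind the package.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Networks, states, normalization

A `BooleanNetwork` is an ordered tuple of variables with one truth table per
variable.  Functions are kept in a canonical semantic form: inputs sorted by
declaration order, every listed input essential (some flip of it changes the
output), tables indexed with the first input as the least significant bit.
Normalization happens at construction, so degrees, self-regulation and the
interaction graph are semantic properties, not syntactic ones: `A, B & !B |
A` parses to the identity of `A`.  States are integers with bit *i* holding
variable *i*; printed state strings list variable 0 first, matching the
`0*1*` subspace notation.  Truth tables are explicit, so a hard cap of 20
inputs per function applies to parsing and substitution (a desk-scale guard;
violations raise, and ensemble pipelines count them as skipped).

Edge signs come from exhaustive flip analysis: +1 if flipping the input can
only increase the output, -1 if only decrease, 0 (dual) if both occur.

## Dynamics

Attractors are terminal strongly connected components of the explicit STG,
computed with sparse strong-component analysis over vectorized successor
arrays.  The asynchronous STG omits non-changing self-transitions, so fixed
points are the zero-out-degree states; the synchronous STG has exactly one
successor per state.  Explicit analysis is guarded at 22 variables.
Attractor identity and report order are keyed by the smallest member state,
making all outputs deterministic.

Trap spaces are checked on the functions (restricted-cube evaluation), never
by state enumeration, and are scheme-independent.  The smallest enclosing
trap space of a state set starts from the componentwise span and repeatedly
frees violated fixed variables; trap spaces are intersection-closed, so the
fixpoint is the unique smallest one.  Minimal trap spaces come from two
interchangeable engines: a depth-first branching search over partial
assignments (default, capacity 28 free variables) whose pruning rule is an
exact completability test — given the variables already decided, can the
undecided ones still be fixed so that the assigned variable's function is
constant on the final cube — and a 3^N brute-force scan (the oracle, up to
12 variables).  The two engines are asserted equal on random networks up to
N = 8.

A complex attractor is motif-avoidant iff its smallest enclosing trap space
is not minimal; minimality is decided by searching for a proper sub-trap
space inside it.  This is equivalent to "contained in no minimal trap
space" (containment of one attractor state implies containment of the whole
strongly connected attractor) and is cross-checked against that direct
definition in the tests.  For each avoided minimal trap space the report
carries (M, d, m): M = free count of the smallest trap space containing the
attractor *and* that trap space, d = oscillating variables, m = minimal
Hamming disagreement of an attractor state with the trap space's fixed
values restricted to the oscillating variables.  m = 0 is possible when the
trap space differs from the attractor only on frozen variables; the delay
bound below is defined for 1 <= m < d and validates its inputs.

## Structural exclusion

The exclusion verdict tests, in order: no cycle; only positive cycles; only
negative cycles; no path from a non-positive cycle (sign product -1 or an
ambiguous edge) to a non-negative cycle (+1 or ambiguous); L-cuttability.
Ambiguous edges count as both signs throughout.

Non-positive-cycle existence is decided exactly by the parity-doubled graph:
an odd closed walk decomposes into simple cycles with parities summing odd,
so one is odd.  The even-direction analogue fails (two odd cycles through a
vertex yield an even walk without an even cycle), and exact even-cycle
detection in digraphs is a substantially harder problem; non-negative cycles
and the vertex sets feeding the path criterion therefore come from simple-
cycle enumeration with a 100 000-cycle budget and early saturation.  If the
budget is ever exhausted the unresolved flags fall back to "cycle present",
which can only make exclusion less aggressive — the verdict stays sound, and
soundness (excluded implies no MAA) is property-tested on 1000 random
critical networks.

L-cuttability removes all linear nodes (in- and out-degree one) and requires
the remainder acyclic with no edge-path from a branching to a merging node.
Zero-length paths do not violate the cut: a node with both multiple targets
and multiple regulators is acceptable as long as every edge-path through it
passes a linear node, which is exactly why extending every edge of any graph
produces an L-cuttable one.  In L-cuttable networks the tests assert the
attractor/minimal-trap-space bijection.

## Reduction

`delete_node` substitutes a non-self-regulating variable's function into its
targets and re-normalizes, so substitution-created identities (`X | !X`)
simplify to constants — the mechanism by which reduction both creates MAAs
(deleting a linear node can merge a delay back into a motif-avoidant core)
and destroys them (a new stable motif traps the oscillation).  Both
directions are asserted: the first on the delayed 2-variable MAA, the second
on a synthetic 3-variable network found by seeded search.

`reduce_max` deletes the eligible variable with the fewest essential inputs
(ties by declaration order) until every remaining variable self-regulates.
This ordering approximates "simplest function first"; reduction endpoints
are order-dependent in general, so ensemble statistics quantify this
pipeline, not all possible reduction orders.  The endpoint retains at least
one variable by default: the empty model is not representable in the
BDD-backed model-manipulation tools this pipeline mirrors, and a lone
constant variable has no target left to substitute into.  `allow_empty=True`
opts into full deletion.  A one-variable network cannot hold an MAA, so this
convention affects mean-size statistics only.

`percolate` fixes variables, propagates newly constant functions to a
fixpoint, and removes every percolated variable; it conditions the dynamics
(an imposed value inconsistent with a self-sustaining loop still removes the
variable, while unforced loops survive) and never adds essential edges.

## Delays

Linear extension of edge u -> v inserts `d_u_v` with the identity function
of u and rewires v to read it; delay variables are appended after the
originals in edge-sorted order, and deleting them recovers the original
network exactly.  States where every delay equals its parent are canonical;
the rest are memory states.  `classify_memory_transitions` compares each
memory state's transitions on original variables with those of its
projection; `projected_stg` maps canonical-to-canonical paths with
memory-only interiors onto original states (self-edges excluded, mirroring
the omission of non-changing self-transitions), retains every original edge,
and labels the rest as gained with one witness path.

"Motif avoidance eliminated" means the extended network has no MAA at all —
the survey counts networks, and a weaker reading (only the original
attractor trapped) would not compose across multiple MAAs.
`single_delay_survey` tries each incoming edge of each oscillating variable
separately; `minimal_delay_set_size` searches subsets of all essential edges
by increasing cardinality (then lexicographic order), so its result carries
a necessity certificate.  The bound `(M - d)(M - 1) + m(m + 1)/2` and its
worst-case form `E_max - (sqrt(E_max) - d/2)(d + 1)` (equal at m = d - 1,
verified numerically for all 2 <= d <= N <= 10) cap the search.

The star family `star_network(N)` uses f_i(x) = 1 iff all variables agree
(x = 00..0 or 11..1), the N-ary generalization of the two-variable XNOR
pair.  Every member has a complete interaction graph (N^2 edges), point
attractor 11..1, an (N+1)-state MAA (zero state plus all weight-1 states),
metrics (N, N, N-1), and a minimal delay count of floor(N^2/4) — certified
exhaustively for N = 2, 3, 4.  The weight-based variant f_i(x) = [weight(x)
!= 1] realizes the same attractor but a *different* basin structure in
which a single self-edge delay already eliminates the N = 3 MAA; the
all-equal realization is the one whose delay counts scale as the family
requires, which is why it is canonical here.

## Canalization

Sensitivity is the mean number of output-changing single-input flips per
state.  Effective connectivity is k minus the mean state redundancy k_r(x),
where k_r(x) averages the wildcard counts of the prime implicants (of the
state's own output class) covering x, unweighted — the unweighted average is
what reproduces the exact rational values of the prototype rules (e.g.
1.5625 for `A | B & C`).  Prime implicants come from Quine-McCluskey
expansion and subsumption.  Both measures are invariant under input
permutation and input/output negation (property-tested).  The critical
ensemble expectation enumerates all 2^(2^k) tables exactly for k <= 4,
weighting by p^ones (1-p)^zeros; conditioning on all inputs essential is
available behind a flag but off by default.  At the critical bias for k = 3
the exact expectations are sensitivity 1 and effective connectivity
~1.34799; both bias roots give identical averages by negation symmetry.

## Random ensembles and experiments

`generate_critical_rbn` draws, per node, K distinct regulators uniformly
from all N nodes (self allowed) and 2^K i.i.d. Bernoulli(p) truth-table
bits, with p the smaller root of 2Kp(1-p) = 1 by default (K = 1 has no
root and uses the variance-maximizing p = 0.5).  Networks are normalized on
construction, so chance-non-essential inputs are pruned before analysis.
Everything is reproducible bit-for-bit from the seed.

The generator emulates the quenched critical N-K ensemble; it does not
emulate features of curated biological models — scale-free degree
structure, dominant canalizing rules, or constant input nodes — so passing
ensemble tests says nothing about any particular curated model beyond what
the structural theorems guarantee.

Experiments and their desk-scale problem sizes (chosen to give three-sigma
binomial resolution around the quantities of interest):

- MAA frequency: 8000 networks at N = K = 10 (the observed likelihood is a
  few percent there; it collapses by orders of magnitude for sparse K = 2
  networks, which the tests check as a ratio).
- Reduction: 2000 networks at N = 10, K = 2 and 1000 at N = 40, K = 2 for
  mean maximally-reduced sizes; 20 000 at N = 10, K = 2 for the
  reduced-network MAA frequency.  Empty-endpoint handling is as above;
  skipped traces (guard trips) leave the denominators.
- Fragility: sampling until 100 MAA-containing networks at N = K = 10, then
  a single-delay survey per MAA, reporting the resistant fraction, the
  histogram of successful-edge counts, and how many MAAs embed the
  two-variable pattern (bidirectional 00<->01, 00<->10 transitions in some
  oscillating-variable plane, up to negation).
- Frequencies are reported with the Wilson-style interval
  (m+2)/(n+4) +/- (2/(n+4)) sqrt(1 + n sigma^2), clipped to [0, 1].

The exhaustive 2-variable classification finds exactly one MAA-containing
class up to relabeling and negation; its orbit has 4 labeled members (the
XOR/XNOR pairs — the variable swap is a stabilizer), so the exact frequency
of MAA networks among unbiased 2-variable draws is 4/256 = 1/64, which the
sampled experiment reproduces.

The 3-variable template survey enumerates all 2^21 asynchronous STGs with
111 a fixed point (vectorized bitboard reachability prefilter), keeps
networks whose unique minimal trap space is 111 and whose single MAA loses
the attractor property when any internal transition is removed, and groups
patterns (state set + internal transitions) up to variable permutation
(negation cannot fix 111).  This permissive convention yields 68 template
classes; coarser equivalences collapse more.  The survey's structural facts
are what the tests pin down: the star-3 pattern and the pure 6-state cycle
are among the templates, and every template with M = d and m = 1 is
destroyed by a delay on a single self-regulation.

## Numerical and engineering choices

- Deterministic ordering everywhere: attractors by smallest state, edges by
  (source, target) declaration indices, subsets lexicographically.
- Guards: 20 inputs per function, 22 variables for explicit STGs, 28 free
  variables for the branching trap-space engine, 12 for the brute-force
  oracle; guard trips raise typed errors and are counted as skips in
  ensembles.
- The delay-name scheme `d_<u>_<v>` refuses collisions with existing
  variables rather than renaming silently.
- `write_bnet` emits greedy prime-implicant DNF covers; parse(write(net)) is
  the identity on normalized networks (property-tested).

## Known limitations

- Explicit-state methods only: no symbolic (BDD) attractor detection, so
  networks beyond ~22 variables are out of reach except through reduction.
- Succession diagrams are not built; only the smallest enclosing trap space
  of an attractor is computed.
- Most-permissive and random-set update schemes are not implemented
  (asynchronous and synchronous only).
- The non-negative-cycle flag is enumeration-based with a budget; on
  adversarial cycle-rich graphs with no non-negative cycle the summary may
  conservatively report one (flagged by `exact=False`), weakening but never
  unsounding the exclusion verdict.
- Reduction statistics are specific to the fewest-inputs-first deletion
  policy; other orders visit other reduced variants.
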