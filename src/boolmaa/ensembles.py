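"""Critical N-K random Boolean networks, fixture families and the
desk-scale frequency / reduction / fragility experiments.

The generator emulates the classical quenched N-K ensemble: each of the N
nodes receives K distinct regulators drawn uniformly (self-regulation
allowed) and a truth table whose 2**K entries are i.i.d. Bernoulli(p).  At
the critical bias, 2Kp(1-p) = 1, the expected average sensitivity is exactly
1 and the ensemble sits at the order-chaos transition; all experiments here
use the smaller root of that equation by default (output negation makes the
two roots statistically equivalent).

Experiments report binomial frequencies with the Wilson-style 95% interval
(m+2)/(n+4) +/- (2/(n+4)) * sqrt(1 + n * var).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, permutations, product

import numpy as np

from .delays import single_delay_survey
from .dynamics import (SizeGuardError, STG_VARIABLE_LIMIT, MAAReport, Subspace,
                       attractors, find_maas, has_maa, minimal_trap_spaces)
from .network import BooleanNetwork
from .reduction import reduce_max

__all__ = [
    "critical_p",
    "critical_p_roots",
    "EnsembleConfig",
    "ExperimentResult",
    "generate_critical_rbn",
    "star_network",
    "enumerate_2var_classes",
    "wilson_interval",
    "maa_frequency_experiment",
    "reduction_experiment",
    "fragility_experiment",
    "detect_embedded_2var",
    "Template",
    "prototype_survey_3var",
    "prototype_survey_2var",
]


# ---------------------------------------------------------------------------
# Critical bias and network generation
# ---------------------------------------------------------------------------

def critical_p_roots(K: int) -> tuple[float, float]:
    """Both roots of 2Kp(1-p) = 1 (equal for K <= 2)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K < 2:
        return 0.5, 0.5
    disc = math.sqrt(1.0 - 2.0 / K)
    return (1.0 - disc) / 2.0, (1.0 + disc) / 2.0


def critical_p(K: int) -> float:
    """The smaller root of 2Kp(1-p) = 1 (0.5 for K <= 2)."""
    return critical_p_roots(K)[0]


@dataclass
class EnsembleConfig:
    """Parameters of one random-ensemble experiment.

    ``p`` defaults to the critical bias for ``K``.  ``samples`` is the
    fixed-sample stop rule; ``maa_target`` the fixed-positive-count rule used
    by the fragility experiment.  Networks whose analysis trips a size or
    input guard are recorded as skipped and excluded from denominators.
    """

    N: int
    K: int
    p: float | None = None
    seed: int = 0
    samples: int | None = None
    maa_target: int | None = None
    max_inputs: int = 20

    def __post_init__(self):
        if not (1 <= self.K <= self.N):
            raise ValueError(f"need 1 <= K <= N, got K={self.K}, N={self.N}")
        if self.p is None:
            self.p = critical_p(self.K)
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"bias p must be in (0, 1), got {self.p}")


@dataclass
class ExperimentResult:
    """Outcome of one ensemble experiment."""

    samples: int
    positives: int
    skipped: int
    frequency: float
    wilson: tuple[float, float]
    aux: dict = field(default_factory=dict)
    records: list = field(default_factory=list)


def generate_critical_rbn(cfg: EnsembleConfig,
                          rng: np.random.Generator | None = None
                          ) -> BooleanNetwork:
    """One N-K random network: K distinct regulators per node (uniform,
    self allowed), truth-table bits i.i.d. Bernoulli(p).

    Construction normalizes the functions, so non-essential inputs drawn by
    chance are pruned from the returned network.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    N, K, p = cfg.N, cfg.K, cfg.p
    names = [f"x{i}" for i in range(N)]
    functions = {}
    for i in range(N):
        regs = np.sort(rng.choice(N, size=K, replace=False))
        table = (rng.random(1 << K) < p).astype(np.uint8)
        functions[names[i]] = (tuple(names[r] for r in regs), table)
    return BooleanNetwork(functions, variables=names)


def star_network(N: int) -> BooleanNetwork:
    """The star-shaped family: every variable turns ON exactly when all
    variables agree, f_i(x) = 1 iff x is 00..0 or 11..1.

    Every member has a complete interaction graph (N**2 edges), the point
    attractor 11..1, and a motif-avoidant attractor of N+1 states (the zero
    state plus all weight-1 states, arranged as a star around 00..0).  N=2
    is the unique two-variable network with a motif-avoidant attractor (both
    functions XNOR).  The all-ones trap state is unreachable from the rest
    of the state space — the update-order requirement for reaching it is
    circular — and the minimal number of single-edge delays that destroys
    the attractor is floor(N**2/4).
    """
    if N < 2:
        raise ValueError("the star family starts at N = 2")
    if N > 12:
        raise ValueError("star networks beyond N = 12 exceed the table guard")
    names = [chr(ord("A") + i) for i in range(N)]
    states = np.arange(1 << N, dtype=np.int64)
    table = ((states == 0) | (states == (1 << N) - 1)).astype(np.uint8)
    functions = {name: (tuple(names), table) for name in names}
    return BooleanNetwork(functions, variables=names)


# ---------------------------------------------------------------------------
# Exhaustive 2-variable classification
# ---------------------------------------------------------------------------

def _transform_2var(tables: tuple[int, int], perm, negs) -> tuple[int, int]:
    """Conjugate a 2-variable network by a variable permutation + negation.

    ``tables`` encodes f_0, f_1 as 4-bit integers over inputs (x0, x1), x0
    the least significant index bit.  The symmetry phi(x)_i = x_perm(i) XOR
    negs_i acts on states; the transformed network is phi . F . phi^{-1}.
    """
    def phi_inv(y):
        # x_perm(i) = y_i XOR negs_i
        x = 0
        for i in range(2):
            x |= ((y >> i) & 1 ^ negs[i]) << perm[i]
        return x

    out = []
    for i in range(2):
        t = 0
        for y in range(4):
            x = phi_inv(y)
            val = (tables[perm[i]] >> x) & 1 ^ negs[i]
            t |= val << y
        out.append(t)
    return tuple(out)


def _net_from_2var_tables(tables: tuple[int, int]) -> BooleanNetwork:
    funcs = {}
    for i, name in enumerate(("A", "B")):
        table = np.array([(tables[i] >> x) & 1 for x in range(4)], dtype=np.uint8)
        funcs[name] = (("A", "B"), table)
    return BooleanNetwork(funcs)


def enumerate_2var_classes() -> tuple[int, list[BooleanNetwork], dict]:
    """Classify all 256 two-variable networks by asynchronous motif
    avoidance, up to variable relabeling and negation.

    Returns (number of MAA-containing classes, one representative network
    per such class, orbit map {representative tables: orbit set}).
    """
    group = [(perm, negs) for perm in permutations(range(2))
             for negs in product((0, 1), repeat=2)]
    orbits: dict[tuple[int, int], set] = {}
    seen: set[tuple[int, int]] = set()
    for t0 in range(16):
        for t1 in range(16):
            tb = (t0, t1)
            if tb in seen:
                continue
            orbit = {_transform_2var(tb, perm, negs) for perm, negs in group}
            seen |= orbit
            orbits[min(orbit)] = orbit
    flagged = []
    for rep in sorted(orbits):
        if has_maa(_net_from_2var_tables(rep)):
            flagged.append(_net_from_2var_tables(rep))
    return len(flagged), flagged, orbits


# ---------------------------------------------------------------------------
# Wilson interval
# ---------------------------------------------------------------------------

def wilson_interval(n: int, m: int, var: float) -> tuple[float, float]:
    """95% interval (m+2)/(n+4) +/- (2/(n+4)) sqrt(1 + n var), clipped to
    [0, 1]."""
    if n < 1 or not (0 <= m <= n) or var < 0:
        raise ValueError(f"invalid interval inputs n={n}, m={m}, var={var}")
    center = (m + 2) / (n + 4)
    half = 2.0 / (n + 4) * math.sqrt(1.0 + n * var)
    return max(0.0, center - half), min(1.0, center + half)


def _binary_wilson(n: int, m: int) -> tuple[float, float]:
    q = m / n if n else 0.0
    return wilson_interval(n, m, q * (1.0 - q)) if n else (0.0, 1.0)


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def maa_frequency_experiment(cfg: EnsembleConfig,
                             keep_records: bool = False) -> ExperimentResult:
    """Frequency of networks with at least one motif-avoidant attractor."""
    if cfg.samples is None:
        raise ValueError("maa_frequency_experiment needs cfg.samples")
    rng = np.random.default_rng(cfg.seed)
    positives = skipped = 0
    records = []
    for idx in range(cfg.samples):
        net = generate_critical_rbn(cfg, rng)
        try:
            if net.n > STG_VARIABLE_LIMIT:
                raise SizeGuardError(str(net.n))
            flag = has_maa(net)
        except SizeGuardError:
            skipped += 1
            continue
        positives += flag
        if keep_records:
            records.append({"index": idx, "maa": bool(flag)})
    n = cfg.samples - skipped
    freq = positives / n if n else 0.0
    return ExperimentResult(cfg.samples, positives, skipped, freq,
                            _binary_wilson(n, positives), records=records)


def reduction_experiment(cfg: EnsembleConfig,
                         keep_records: bool = False) -> ExperimentResult:
    """Maximally reduce each sampled network and test the result for MAAs.

    Reports the MAA frequency of the reduced networks plus auxiliary means:
    reduced size (with its standard error; empty networks count as size 0
    and as MAA-free) and interactions per variable over non-empty reduced
    networks.
    """
    if cfg.samples is None:
        raise ValueError("reduction_experiment needs cfg.samples")
    rng = np.random.default_rng(cfg.seed)
    positives = skipped = 0
    sizes: list[int] = []
    interactions: list[float] = []
    records = []
    for idx in range(cfg.samples):
        net = generate_critical_rbn(cfg, rng)
        trace = reduce_max(net, max_inputs=cfg.max_inputs)
        if trace.skipped or trace.final.n > STG_VARIABLE_LIMIT:
            skipped += 1
            continue
        reduced = trace.final
        sizes.append(reduced.n)
        if reduced.n:
            interactions.append(reduced.n_edges() / reduced.n)
        flag = reduced.n > 0 and has_maa(reduced)
        positives += flag
        if keep_records:
            records.append({"index": idx, "reduced_size": reduced.n,
                            "maa": bool(flag)})
    n = cfg.samples - skipped
    freq = positives / n if n else 0.0
    arr = np.array(sizes, dtype=float)
    aux = {
        "mean_reduced_size": float(arr.mean()) if n else float("nan"),
        "sem_reduced_size": float(arr.std(ddof=1) / math.sqrt(len(arr)))
        if len(arr) > 1 else float("nan"),
        "mean_interactions_per_variable": float(np.mean(interactions))
        if interactions else float("nan"),
    }
    return ExperimentResult(cfg.samples, positives, skipped, freq,
                            _binary_wilson(n, positives), aux=aux,
                            records=records)


def detect_embedded_2var(net: BooleanNetwork, report: MAAReport) -> bool:
    """Whether the four-state two-variable motif-avoidance pattern embeds in
    the attractor.

    True iff two oscillating variables u, v and a fixing of all others exist
    such that, up to negation of u and v, the plane contains the transitions
    {00<->01, 00<->10} with 00, 01, 10 attractor states.
    """
    if not report.is_motif_avoidant:
        raise ValueError("the report does not describe a motif-avoidant attractor")
    att = set(report.attractor.states)
    vals = net.values_on_all_states()

    def has_transition(x: int, i: int) -> bool:
        return vals[x, i] != (x >> i) & 1

    osc_idx = [net.index(v) for v in report.attractor.oscillating]
    for iu, iv in combinations(osc_idx, 2):
        for s in report.attractor.states:
            base = s & ~(1 << iu) & ~(1 << iv)
            for a0, b0 in product((0, 1), repeat=2):
                q00 = base | (a0 << iu) | (b0 << iv)
                q01 = q00 ^ (1 << iv)
                q10 = q00 ^ (1 << iu)
                if not {q00, q01, q10} <= att:
                    continue
                if (has_transition(q00, iv) and has_transition(q01, iv)
                        and has_transition(q00, iu) and has_transition(q10, iu)):
                    return True
    return False


def fragility_experiment(cfg: EnsembleConfig, maa_target: int | None = None,
                         max_samples: int | None = None) -> ExperimentResult:
    """Sample until ``maa_target`` MAA-containing networks are found, then
    test each motif-avoidant attractor against every single-edge delay.

    The ``aux`` dict reports the fraction of MAAs that no single delay
    destroys, the histogram of successful-edge counts, and how many MAAs
    embed the two-variable pattern.
    """
    if maa_target is None:
        maa_target = cfg.maa_target
    if maa_target is None:
        raise ValueError("fragility_experiment needs a positive-count target")
    rng = np.random.default_rng(cfg.seed)
    samples = skipped = 0
    n_maas = resistant = embedded = 0
    histogram: dict[int, int] = {}
    positives = 0
    while positives < maa_target:
        if max_samples is not None and samples >= max_samples:
            break
        samples += 1
        net = generate_critical_rbn(cfg, rng)
        try:
            reports = find_maas(net, include_metrics=False)
        except SizeGuardError:
            skipped += 1
            continue
        if not reports:
            continue
        positives += 1
        for report in reports:
            try:
                _, n_success = single_delay_survey(net, report)
            except SizeGuardError:
                skipped += 1
                continue
            n_maas += 1
            histogram[n_success] = histogram.get(n_success, 0) + 1
            resistant += n_success == 0
            embedded += detect_embedded_2var(net, report)
    n = samples - skipped
    freq = positives / n if n else 0.0
    aux = {
        "n_maas": n_maas,
        "resistant_fraction": resistant / n_maas if n_maas else float("nan"),
        "success_histogram": dict(sorted(histogram.items())),
        "embedded_2var": embedded,
    }
    return ExperimentResult(samples, positives, skipped, freq,
                            _binary_wilson(n, positives), aux=aux)


# ---------------------------------------------------------------------------
# Prototypical templates: edge-minimal motif avoidance with trap state 11..1
# ---------------------------------------------------------------------------

@dataclass
class Template:
    """An edge-minimal motif-avoidance pattern avoiding the all-ones state.

    ``states`` is the attractor state set, ``internal_edges`` its transitions
    (as (state, variable-index) toggles), ``network`` one representative,
    ``eliminating_edges`` the interaction-graph edges whose single linear
    extension destroys the attractor, and ``metrics`` the (M, d, m) triple.
    """

    states: tuple[int, ...]
    internal_edges: tuple[tuple[int, int], ...]
    network: BooleanNetwork
    eliminating_edges: tuple[tuple[str, str], ...]
    metrics: tuple[int, int, int]


def _toggles_to_network(toggles: np.ndarray, nvars: int) -> BooleanNetwork:
    """Network whose asynchronous STG has exactly the given toggles;
    toggles[s, i] == 1 means updating variable i changes state s."""
    names = [chr(ord("A") + i) for i in range(nvars)]
    states = np.arange(1 << nvars)
    funcs = {}
    for i in range(nvars):
        bits = ((states >> i) & 1).astype(np.uint8) ^ toggles[:, i].astype(np.uint8)
        funcs[names[i]] = (tuple(names), bits)
    return BooleanNetwork(funcs)


def _pattern_canonical(states: tuple[int, ...], edges, nvars: int):
    """Canonical form of (state set, internal toggles) under variable
    permutation (negation cannot fix the all-ones trap state)."""
    best = None
    for perm in permutations(range(nvars)):
        def psi(s):
            out = 0
            for i in range(nvars):
                out |= ((s >> i) & 1) << perm[i]
            return out
        cand = (tuple(sorted(psi(s) for s in states)),
                tuple(sorted((psi(s), perm[i]) for s, i in edges)))
        if best is None or cand < best:
            best = cand
    return best


def _template_from_config(net: BooleanNetwork, nvars: int):
    """MAA + trap-space checks shared by the 2- and 3-variable surveys.

    Requires: the unique minimal trap space is the all-ones point, the
    network has a motif-avoidant attractor, and removing any transition
    among attractor states destroys that attractor (edge-minimality).
    Returns (states, internal_edges, report) or None.
    """
    all_ones = (1 << nvars) - 1
    mts = minimal_trap_spaces(net)
    if mts != [Subspace.from_state(all_ones, nvars)]:
        return None
    reports = find_maas(net, include_metrics=False)
    if len(reports) != 1:
        return None
    report = reports[0]
    states = set(report.attractor.states)
    vals = net.values_on_all_states()
    internal = [(s, i) for s in sorted(states) for i in range(nvars)
                if vals[s, i] != (s >> i) & 1 and (s ^ (1 << i)) in states]
    for s, i in internal:
        pruned = vals.copy()
        pruned[s, i] = (s >> i) & 1
        toggles = pruned ^ ((np.arange(1 << nvars)[:, None] >>
                             np.arange(nvars)[None, :]) & 1).astype(np.uint8)
        modified = _toggles_to_network(toggles, nvars)
        if any(set(a.states) == states for a in attractors(modified)):
            return None  # the transition was not needed: not edge-minimal
    return tuple(sorted(states)), tuple(internal), report


def _finalize_templates(candidates: list[tuple[np.ndarray, int]], nvars: int
                        ) -> list[Template]:
    templates: dict = {}
    for toggles, _cfg in candidates:
        net = _toggles_to_network(toggles, nvars)
        res = _template_from_config(net, nvars)
        if res is None:
            continue
        states, internal, report = res
        key = _pattern_canonical(states, internal, nvars)
        if key in templates:
            continue
        verdicts, _ = single_delay_survey(net, report)
        elim = tuple(sorted(e for e, ok in verdicts.items() if ok))
        from .dynamics import maa_metrics
        tmin = Subspace.from_state((1 << nvars) - 1, nvars)
        templates[key] = Template(states=states, internal_edges=internal,
                                  network=net, eliminating_edges=elim,
                                  metrics=maa_metrics(net, report, tmin,
                                                      validate=False))
    return [templates[k] for k in sorted(templates)]


def prototype_survey_2var() -> list[Template]:
    """Two-variable analog of the template survey (64 candidate STGs)."""
    nvars = 2
    candidates = []
    for cfg in range(1 << (2 * 3)):
        toggles = np.zeros((4, 2), dtype=np.uint8)
        for s in range(3):
            for i in range(2):
                toggles[s, i] = (cfg >> (2 * s + i)) & 1
        candidates.append((toggles, cfg))
    return _finalize_templates(candidates, nvars)


def _survivor_configs_3var() -> np.ndarray:
    """Vectorized pre-filter over all 2**21 three-variable STG configs.

    A config packs the toggle bits of the seven non-111 states (bit 3s+i:
    updating variable i changes state s; 111 is forced to be a fixed point).
    Keeps permutation-canonical configs that have no other fixed point and
    at least one complex terminal SCC avoiding 111.
    """
    cfgs = np.arange(1 << 21, dtype=np.uint64)
    ok = np.ones(cfgs.shape, dtype=bool)
    for s in range(7):
        ok &= ((cfgs >> np.uint64(3 * s)) & np.uint64(7)) != 0
    cfgs = cfgs[ok]
    # canonical representative under the 6 variable permutations
    best = cfgs.copy()
    for perm in permutations(range(3)):
        if perm == (0, 1, 2):
            continue
        mapped = np.zeros_like(cfgs)
        for s in range(7):
            psi = sum(((s >> i) & 1) << perm[i] for i in range(3))
            for i in range(3):
                bit = (cfgs >> np.uint64(3 * s + i)) & np.uint64(1)
                mapped |= bit << np.uint64(3 * psi + perm[i])
        np.minimum(best, mapped, out=best)
    cfgs = cfgs[cfgs == best]
    # adjacency bitboards (8 bytes = 8 state rows), identity included
    R = np.zeros_like(cfgs)
    for s in range(8):
        R |= np.uint64(1 << (8 * s + s))
    for s in range(7):
        for i in range(3):
            bit = (cfgs >> np.uint64(3 * s + i)) & np.uint64(1)
            R |= bit << np.uint64(8 * s + (s ^ (1 << i)))
    for _ in range(3):  # transitive closure by squaring (paths up to length 8)
        newR = R.copy()
        for r in range(8):
            for j in range(8):
                has = (R >> np.uint64(8 * r + j)) & np.uint64(1)
                rowj = (R >> np.uint64(8 * j)) & np.uint64(0xFF)
                newR |= (rowj * has) << np.uint64(8 * r)
        R = newR
    T = np.zeros_like(R)
    for r in range(8):
        for j in range(8):
            T |= ((R >> np.uint64(8 * r + j)) & np.uint64(1)) << np.uint64(8 * j + r)
    S = R & T
    pop = np.array([bin(x).count("1") for x in range(256)], dtype=np.uint8)
    keep = np.zeros(cfgs.shape, dtype=bool)
    for s in range(7):
        reach = ((R >> np.uint64(8 * s)) & np.uint64(0xFF)).astype(np.int64)
        scc = ((S >> np.uint64(8 * s)) & np.uint64(0xFF)).astype(np.int64)
        terminal = reach == scc
        complex_ = pop[scc] >= 2
        avoid = (scc >> 7) & 1 == 0
        keep |= terminal & complex_ & avoid
    return cfgs[keep]


def prototype_survey_3var() -> list[Template]:
    """Exhaustive survey of edge-minimal three-variable motif-avoidance
    templates with minimal trap space 111.

    Enumerates all asynchronous STGs on three variables with 111 a fixed
    point, keeps networks whose unique minimal trap space is 111 and whose
    motif-avoidant attractor loses the attractor property when any of its
    internal transitions is removed, and groups the resulting patterns up to
    variable permutation.
    """
    cfgs = _survivor_configs_3var()
    candidates = []
    for cfg in cfgs.tolist():
        toggles = np.zeros((8, 3), dtype=np.uint8)
        for s in range(7):
            for i in range(3):
                toggles[s, i] = (cfg >> (3 * s + i)) & 1
        candidates.append((toggles, cfg))
    return _finalize_templates(candidates, 3)
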